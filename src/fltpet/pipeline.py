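"""Orchestration of the two analyses: the test-retest reproducibility study
(duplicate baseline scans, reproducibility model) and the radiotherapy
response study (baseline vs on-treatment scans, response model with optional
BED covariate). Reports are plain dictionaries suitable for JSON export; the
CLI renders them to files.
"""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np
import pandas as pd

from . import mixed_model, reproducibility, response, synthetic
from .response import RTSchedule

log = logging.getLogger("fltpet")

PARAMETERS = ("volume", "suv_mean", "suv_max")
_PARAM_COLUMNS = {"volume": "volume_cm3", "suv_mean": "suv_mean", "suv_max": "suv_max"}

__all__ = [
    "model_input_from_cohort",
    "run_reproducibility",
    "run_response",
    "run_demo",
]


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def model_input_from_cohort(cohort: pd.DataFrame, parameter: str, model: str = "B"):
    """Pair scans per lesion for the offset ANCOVA.

    Model A (reproducibility): y0 = Scan1, y1 = Scan2. Model B (response):
    y0 = latest baseline (S2 if present, else S1), y1 = Scan3. Lesions
    missing a required scan are dropped listwise.
    """
    col = _PARAM_COLUMNS[parameter]
    y0, y1, pats, nodes, lesions = [], [], [], [], []
    for (pid, lid), grp in cohort.groupby(["patient_id", "lesion_id"], sort=True):
        scans = {row.scan_label: row for row in grp.itertuples()}
        if model == "A":
            if "S1" not in scans or "S2" not in scans:
                continue
            pre, post = scans["S1"], scans["S2"]
        elif model == "B":
            if "S3" not in scans or ("S1" not in scans and "S2" not in scans):
                continue
            pre = scans.get("S2", scans.get("S1"))
            post = scans["S3"]
        else:
            raise ValueError("model must be 'A' or 'B'")
        y0.append(float(getattr(pre, col)))
        y1.append(float(getattr(post, col)))
        pats.append(str(pid))
        nodes.append(1.0 if post.lesion_type == "node" else 0.0)
        lesions.append(str(lid))
    if not y0:
        raise ValueError(f"cohort has no lesions evaluable for model {model}")
    return (
        np.array(y0),
        np.array(y1),
        np.array(pats),
        np.array(nodes),
        np.array(lesions),
    )


def _fit_summary(fit: mixed_model.MixedModelFit) -> dict:
    out = {
        "beta0": fit.beta0,
        "se_beta0": float(fit.se[0]),
        "p_beta0": float(fit.p_values[0]),
        "sigma_b2": fit.sigma_b2,
        "sigma2": fit.sigma2,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "variance_partition_pct": 100.0 * fit.variance_partition,
        "effect_primary_pct": fit.effect_primary_pct,
        "effect_primary_ci": fit.effect_primary_ci,
        "n_patients": fit.n_patients,
        "n_lesions": fit.n_lesions,
        "boundary": fit.boundary,
        "warnings": fit.warnings,
    }
    if fit.beta1 is not None:
        i = fit.term_names.index("node")
        out.update(
            beta1=fit.beta1,
            se_beta1=float(fit.se[i]),
            p_beta1=float(fit.p_values[i]),
            effect_node_pct=fit.effect_node_pct,
            effect_node_ci=fit.effect_node_ci,
        )
    return out


def run_reproducibility(
    cohort: pd.DataFrame,
    averaging: str = "lesion",
    method: str = "ml",
    seed: int | None = None,
) -> dict:
    """Test-retest summary, reproducibility-model fits and size-dependence.

    Volume reproducibility is summarized per lesion type (its precision
    depends on lesion size) while SUV reproducibility is additionally
    summarized jointly across types.
    """
    records = reproducibility.build_test_retest_records(cohort)
    if not records:
        raise ValueError("cohort has no duplicate-baseline (S1+S2) lesions")
    n_lesions = len({(r.patient_id, r.lesion_id) for r in records})
    log.info("reproducibility stage: %d lesions with duplicate baselines", n_lesions)

    summaries = {}
    for param in PARAMETERS:
        summaries[param] = {}
        for group in ("primaries", "nodes", "all"):
            try:
                s = reproducibility.summarize_reproducibility(
                    records, param, group, averaging=averaging
                )
                summaries[param][group] = s.__dict__
            except ValueError:
                summaries[param][group] = None

    fits = {}
    for param in PARAMETERS:
        y0, y1, pats, nodes, _ = model_input_from_cohort(cohort, param, model="A")
        fits[param] = _fit_summary(
            mixed_model.fit_ancova(y0, y1, pats, nodes, method=method)
        )

    size_dep = {}
    for param in PARAMETERS:
        try:
            r = reproducibility.size_dependence(records, param)
            size_dep[param] = {"rho": r.rho, "p": r.p_two_sided, "n": r.n}
        except ValueError:
            size_dep[param] = None

    return {
        "stage": "reproducibility",
        "seed": seed,
        "config_hash": _config_hash({"averaging": averaging, "method": method, "seed": seed}),
        "n_lesions": n_lesions,
        "summaries": summaries,
        "model_fits": fits,
        "size_dependence": size_dep,
    }


def run_response(
    cohort: pd.DataFrame,
    schedules: dict[str, RTSchedule] | None = None,
    include_bed: bool = False,
    method: str = "ml",
    seed: int | None = None,
) -> dict:
    """Response summary, per-lesion classification against the repeatability
    coefficient, and response-model fits (optionally extended with BED)."""
    if include_bed and not schedules:
        raise ValueError("BED covariate requested but no RT schedules provided")

    rc_by_param = None
    try:
        repro_records = reproducibility.build_test_retest_records(cohort)
        if repro_records:
            rc_by_param = {}
            for param in PARAMETERS:
                if param == "volume":
                    # size-dependent precision: per-type RC
                    for group, ltype in (("primaries", "primary"), ("nodes", "node")):
                        s = reproducibility.summarize_reproducibility(repro_records, param, group)
                        rc_by_param[(param, ltype)] = (s.rc_pct, s.mean_diff_pct)
                else:
                    s = reproducibility.summarize_reproducibility(repro_records, param, "all")
                    rc_by_param[param] = (s.rc_pct, s.mean_diff_pct)
    except ValueError:
        rc_by_param = None

    records = response.build_response_records(cohort, schedules=schedules, rc_by_param=rc_by_param)
    if not records:
        raise ValueError("cohort has no response-evaluable (baseline+S3) lesions")
    n_lesions = len({(r.patient_id, r.lesion_id) for r in records})
    log.info("response stage: %d evaluable lesions", n_lesions)

    summaries = {
        param: {
            group: _try(response.summarize_response, records, param, group)
            for group in ("primaries", "nodes", "all")
        }
        for param in PARAMETERS
    }

    fits = {}
    for param in PARAMETERS:
        y0, y1, pats, nodes, lesion_ids = model_input_from_cohort(cohort, param, model="B")
        if include_bed:
            bed_by_pat = {pid: response.bed(s) for pid, s in schedules.items()}
            missing = [p for p in pats if p not in bed_by_pat]
            if missing:
                raise ValueError(f"missing RT schedule for patients: {sorted(set(missing))}")
            bed_vals = np.array([bed_by_pat[p] for p in pats])
            base, ext, daic = mixed_model.fit_ancova_with_covariate(
                y0, y1, pats, nodes, bed_vals, method=method
            )
            fits[param] = {
                "base": _fit_summary(base),
                "with_bed": _fit_summary(ext) if ext is not None else None,
                "delta_aic": daic,
            }
            if ext is None:
                log.info("%s: BED covariate constant; extended model skipped", param)
        else:
            fits[param] = {
                "base": _fit_summary(
                    mixed_model.fit_ancova(y0, y1, pats, nodes, method=method)
                )
            }

    classification_counts = {}
    for param in PARAMETERS:
        counts = {"exceeds_decrease": 0, "within": 0, "exceeds_increase": 0, "unclassified": 0}
        for r in records:
            if r.parameter != param:
                continue
            counts[r.classification or "unclassified"] += 1
        classification_counts[param] = counts

    return {
        "stage": "response",
        "seed": seed,
        "config_hash": _config_hash({"include_bed": include_bed, "method": method, "seed": seed}),
        "n_lesions": n_lesions,
        "summaries": summaries,
        "model_fits": fits,
        "classification_counts": classification_counts,
        "records": [r.__dict__ for r in records],
    }


def _try(fn, *args):
    try:
        return fn(*args)
    except ValueError:
        return None


def run_demo(seed: int = 0, n_patients: int | None = None) -> dict:
    """One-command synthetic end-to-end demo: generate the reference cohort,
    run both analyses, and fit the response model with a BED covariate from a
    conventional 55 Gy / 20-fraction schedule truncated at the response scan."""
    cfg = synthetic.reference_cohort_config(seed=seed, n_patients=n_patients)
    cohort = synthetic.generate_cohort(cfg)
    rng = np.random.default_rng(seed + 1)
    patients = sorted(cohort.patient_id.unique())
    schedules = {
        pid: RTSchedule(n_fractions=int(rng.integers(5, 12)), dose_per_fraction_Gy=2.75)
        for pid in patients
    }
    repro = run_reproducibility(cohort, seed=seed)
    resp = run_response(cohort, schedules=schedules, include_bed=True, seed=seed)
    return {"seed": seed, "cohort_rows": len(cohort), "reproducibility": repro, "response": resp}
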