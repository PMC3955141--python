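"""Test-retest reproducibility of lesion imaging parameters.

The percentage test-retest difference of duplicate baseline scans is
(Scan2 - Scan1) / (Scan1 + Scan2) * 200, i.e. the difference relative to the
pair mean; it is antisymmetric under scan swap and bounded in (-200, 200).
Reproducibility is summarized as the SD of these differences across lesions
(optionally across patient means), the mean absolute difference ("absolute
reproducibility"), and the repeatability coefficient RC = 1.96 x SD — the
threshold a longitudinal change must exceed to be distinguishable from
measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats

PARAMETERS = ("volume", "suv_mean", "suv_max")
_PARAM_COLUMNS = {"volume": "volume_cm3", "suv_mean": "suv_mean", "suv_max": "suv_max"}

__all__ = [
    "TestRetestRecord",
    "ReproducibilitySummary",
    "test_retest_difference",
    "build_test_retest_records",
    "summarize_reproducibility",
    "size_dependence",
    "classify_change",
]


@dataclass(frozen=True)
class TestRetestRecord:
    __test__ = False  # domain object, not a pytest class

    patient_id: str
    lesion_id: str
    lesion_type: str
    parameter: str
    scan1_value: float
    scan2_value: float
    diff_pct: float


@dataclass(frozen=True)
class ReproducibilitySummary:
    parameter: str
    lesion_group: str  # primaries | nodes | all
    n: int
    mean_diff_pct: float
    sd_diff_pct: float
    abs_repro_pct: float
    rc_pct: float


def test_retest_difference(scan1, scan2):
    """Percentage difference of a duplicate pair relative to the pair mean."""
    # (pytest: this is a domain operation, not a test)
    s1 = np.asarray(scan1, dtype=float)
    s2 = np.asarray(scan2, dtype=float)
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("scan values must be strictly positive")
    out = (s2 - s1) / (s1 + s2) * 200.0
    return float(out) if out.ndim == 0 else out


test_retest_difference.__test__ = False


def build_test_retest_records(cohort: pd.DataFrame) -> list[TestRetestRecord]:
    """Pair S1/S2 rows of a tidy cohort table into per-parameter records.

    Lesions missing either baseline scan are skipped (listwise per lesion).
    """
    records: list[TestRetestRecord] = []
    for (pid, lid), grp in cohort.groupby(["patient_id", "lesion_id"], sort=True):
        scans = {row.scan_label: row for row in grp.itertuples()}
        if "S1" not in scans or "S2" not in scans:
            continue
        ltype = scans["S1"].lesion_type
        for param, col in _PARAM_COLUMNS.items():
            v1 = float(getattr(scans["S1"], col))
            v2 = float(getattr(scans["S2"], col))
            records.append(
                TestRetestRecord(
                    patient_id=str(pid),
                    lesion_id=str(lid),
                    lesion_type=ltype,
                    parameter=param,
                    scan1_value=v1,
                    scan2_value=v2,
                    diff_pct=test_retest_difference(v1, v2),
                )
            )
    return records


def _group_filter(records, parameter: str, lesion_group: str):
    sel = [r for r in records if r.parameter == parameter]
    if lesion_group == "primaries":
        sel = [r for r in sel if r.lesion_type == "primary"]
    elif lesion_group == "nodes":
        sel = [r for r in sel if r.lesion_type == "node"]
    elif lesion_group != "all":
        raise ValueError("lesion_group must be primaries, nodes or all")
    return sel


def summarize_reproducibility(
    records: list[TestRetestRecord],
    parameter: str,
    lesion_group: str = "all",
    averaging: str = "lesion",
) -> ReproducibilitySummary:
    """Mean, sample SD, mean absolute difference and RC of test-retest diffs.

    averaging="lesion" (default) treats every lesion as one observation;
    averaging="patient" first averages each patient's lesion differences.
    """
    sel = _group_filter(records, parameter, lesion_group)
    if averaging == "lesion":
        diffs = np.array([r.diff_pct for r in sel], dtype=float)
    elif averaging == "patient":
        by_pat: dict[str, list[float]] = {}
        for r in sel:
            by_pat.setdefault(r.patient_id, []).append(r.diff_pct)
        diffs = np.array([np.mean(v) for v in by_pat.values()], dtype=float)
    else:
        raise ValueError("averaging must be 'lesion' or 'patient'")
    n = diffs.size
    if n < 2:
        raise ValueError("need at least 2 observations for an SD")
    sd = float(diffs.std(ddof=1))
    return ReproducibilitySummary(
        parameter=parameter,
        lesion_group=lesion_group,
        n=n,
        mean_diff_pct=float(diffs.mean()),
        sd_diff_pct=sd,
        abs_repro_pct=float(np.abs(diffs).mean()),
        rc_pct=1.96 * sd,
    )


def size_dependence(records: list[TestRetestRecord], parameter: str):
    """Spearman correlation of |test-retest difference| with lesion size.

    Size is the mean of the two baseline values. A significant negative rho
    indicates poorer relative reproducibility for smaller lesions.
    """
    sel = [r for r in records if r.parameter == parameter]
    if len(sel) < 4:
        raise ValueError("need at least 4 paired observations")
    abs_diffs = [abs(r.diff_pct) for r in sel]
    sizes = [(r.scan1_value + r.scan2_value) / 2.0 for r in sel]
    return _stats.spearman(abs_diffs, sizes)


def classify_change(response_pct: float, rc_pct: float, mean_bias_pct: float = 0.0) -> str:
    """Compare a percentage response to the interval mean bias +/- RC.

    The interval is closed: a response exactly at a boundary is 'within'
    (conservative calling of change). Returns one of 'exceeds_decrease',
    'within', 'exceeds_increase'.
    """
    if rc_pct <= 0:
        raise ValueError("RC must be positive")
    lo = mean_bias_pct - rc_pct
    hi = mean_bias_pct + rc_pct
    if response_pct < lo:
        return "exceeds_decrease"
    if response_pct > hi:
        return "exceeds_increase"
    return "within"
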