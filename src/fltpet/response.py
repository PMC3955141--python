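"""Radiotherapy response of lesion imaging parameters and biologically
effective dose (BED).

Response (%) = (Scan3 - Baseline) / Baseline * 100, where Baseline is the
latest (or single) baseline value. BED = n * D * (1 + D / (alpha/beta))
converts a fractionation schedule of n fractions of D Gy into a
linear-quadratic-model equivalent dose; alpha/beta defaults to 10 Gy, the
conventional tumour value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reproducibility import classify_change

_PARAM_COLUMNS = {"volume": "volume_cm3", "suv_mean": "suv_mean", "suv_max": "suv_max"}

__all__ = [
    "RTSchedule",
    "ResponseRecord",
    "percent_response",
    "select_baseline",
    "bed",
    "build_response_records",
    "summarize_response",
]


@dataclass(frozen=True)
class RTSchedule:
    """Fractionation delivered before the response scan."""

    n_fractions: int
    dose_per_fraction_Gy: float
    alpha_beta_Gy: float = 10.0

    def __post_init__(self):
        if self.n_fractions <= 0 or self.dose_per_fraction_Gy <= 0:
            raise ValueError("fraction count and dose per fraction must be positive")
        if self.alpha_beta_Gy <= 0:
            raise ValueError("alpha/beta must be positive")

    @property
    def total_dose_Gy(self) -> float:
        return self.n_fractions * self.dose_per_fraction_Gy


@dataclass(frozen=True)
class ResponseRecord:
    patient_id: str
    lesion_id: str
    lesion_type: str
    parameter: str
    baseline_value: float
    baseline_scan: str  # S1 or S2
    scan3_value: float
    response_pct: float
    bed_Gy: float | None = None
    classification: str | None = None


def percent_response(baseline: float, scan3: float) -> float:
    """Relative change of the on-treatment value vs baseline, in percent."""
    if baseline <= 0:
        raise ValueError("baseline must be strictly positive")
    return (scan3 - baseline) / baseline * 100.0


def select_baseline(values_by_scan: dict[str, float]) -> tuple[float, str]:
    """Latest/single baseline: S2 if present, else S1."""
    if "S2" in values_by_scan:
        return values_by_scan["S2"], "S2"
    if "S1" in values_by_scan:
        return values_by_scan["S1"], "S1"
    raise ValueError("no baseline scan (S1/S2) available")


def bed(schedule: RTSchedule) -> float:
    """Biologically effective dose n*D*(1 + D/(alpha/beta)), in Gy."""
    return schedule.n_fractions * schedule.dose_per_fraction_Gy * (
        1.0 + schedule.dose_per_fraction_Gy / schedule.alpha_beta_Gy
    )


def build_response_records(
    cohort: pd.DataFrame,
    schedules: dict[str, RTSchedule] | None = None,
    rc_by_param: dict | None = None,
) -> list[ResponseRecord]:
    """Per-lesion, per-parameter response records from a tidy cohort table.

    Lesions missing the on-treatment scan (S3) are excluded with a warning,
    not an error. ``schedules`` maps patient_id to the fractionation delivered
    before the response scan (used for BED). ``rc_by_param`` optionally maps
    parameter (or (parameter, lesion_type)) to an (rc_pct, mean_bias_pct) pair
    used to classify each response against measurement noise.
    """
    records: list[ResponseRecord] = []
    for (pid, lid), grp in cohort.groupby(["patient_id", "lesion_id"], sort=True):
        scans = {row.scan_label: row for row in grp.itertuples()}
        if "S3" not in scans:
            warnings.warn(f"lesion {pid}/{lid} has no on-treatment scan; excluded from response")
            continue
        ltype = scans["S3"].lesion_type
        bed_gy = None
        if schedules is not None and str(pid) in schedules:
            bed_gy = bed(schedules[str(pid)])
        for param, col in _PARAM_COLUMNS.items():
            by_scan = {label: float(getattr(row, col)) for label, row in scans.items()}
            baseline, which = select_baseline(by_scan)
            resp = percent_response(baseline, by_scan["S3"])
            classification = None
            if rc_by_param is not None:
                key = (param, ltype) if (param, ltype) in rc_by_param else param
                if key in rc_by_param:
                    rc_pct, bias = rc_by_param[key]
                    classification = classify_change(resp, rc_pct, bias)
            records.append(
                ResponseRecord(
                    patient_id=str(pid),
                    lesion_id=str(lid),
                    lesion_type=ltype,
                    parameter=param,
                    baseline_value=baseline,
                    baseline_scan=which,
                    scan3_value=by_scan["S3"],
                    response_pct=resp,
                    bed_Gy=bed_gy,
                    classification=classification,
                )
            )
    return records


def summarize_response(
    records: list[ResponseRecord],
    parameter: str,
    lesion_group: str = "all",
    include_outliers: bool = True,
    outlier_abs_pct: float = 150.0,
) -> dict:
    """Mean and sample SD of percentage responses for a lesion group.

    All records are included by default (extreme responses are real data);
    setting ``include_outliers=False`` drops |response| > ``outlier_abs_pct``.
    """
    sel = [r for r in records if r.parameter == parameter]
    if lesion_group == "primaries":
        sel = [r for r in sel if r.lesion_type == "primary"]
    elif lesion_group == "nodes":
        sel = [r for r in sel if r.lesion_type == "node"]
    elif lesion_group != "all":
        raise ValueError("lesion_group must be primaries, nodes or all")
    if not include_outliers:
        sel = [r for r in sel if abs(r.response_pct) <= outlier_abs_pct]
    if not sel:
        raise ValueError("empty response group")
    vals = np.array([r.response_pct for r in sel], dtype=float)
    return {
        "parameter": parameter,
        "lesion_group": lesion_group,
        "n": int(vals.size),
        "mean_response_pct": float(vals.mean()),
        "sd_response_pct": float(vals.std(ddof=1)) if vals.size > 1 else None,
    }
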