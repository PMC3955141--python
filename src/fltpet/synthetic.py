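"""Synthetic cohort tables, phantom images and survival data with the exact
statistical structure the downstream analysis assumes.

The cohort generator realizes the random-intercept offset model on the log10
scale. For each patient i a random intercept b_i ~ N(0, sigma_b^2) is drawn
(independently per imaging parameter unless a shared intercept is requested);
each lesion j gets a true baseline log10 value from its lesion type's
baseline distribution; the two baseline scans add independent pure
test-retest noise; and the on-treatment scan is
    log10(S3) = log10(S2) + beta0 + b_i + beta1 * [type == node] + eps_ij,
eps_ij ~ N(0, sigma^2), so that fitting the response model to (S2, S3) pairs
recovers the generating parameters. All values are back-transformed to the
natural scale (hence strictly positive).

Baseline distributions are lognormal with moments matched to published
natural-scale means/SDs of the NSCLC radiotherapy cohort (primaries larger
and hotter than nodes); the reference preset ships 12 patients carrying one
primary and 0-3 nodal lesions each.

Phantoms place ellipsoidal lesions and a bone-marrow box on a uniform
background at a configurable voxel grid, apply Gaussian smoothing of the
scanner's stated FWHM and additive noise; ground-truth masks are returned
pre-smoothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import presets

PARAMETERS = ("volume", "suv_mean", "suv_max")
_PARAM_COLUMNS = {"volume": "volume_cm3", "suv_mean": "suv_mean", "suv_max": "suv_max"}

__all__ = [
    "CohortConfig",
    "PhantomSpec",
    "lognormal_log10_params",
    "reference_cohort_config",
    "generate_cohort",
    "generate_phantom",
    "generate_survival",
]


def lognormal_log10_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal to a natural-scale (mean, SD): returns the
    (mean, SD) of log10(X)."""
    if mean <= 0 or sd < 0:
        raise ValueError("need mean > 0 and sd >= 0")
    ln10 = math.log(10.0)
    s2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    return mu / ln10, math.sqrt(s2) / ln10


def _as_param_map(value, name: str) -> dict:
    """Accept a scalar (broadcast to all parameters) or a per-parameter dict."""
    if isinstance(value, dict):
        missing = set(PARAMETERS) - set(value)
        if missing:
            raise ValueError(f"{name} missing parameters: {sorted(missing)}")
        return {p: float(value[p]) for p in PARAMETERS}
    return {p: float(value) for p in PARAMETERS}


@dataclass
class CohortConfig:
    """Generating parameters of a synthetic lesion cohort.

    Model coefficients (beta0, beta1), variance components (sigma_b2, sigma2),
    test-retest noise and baseline distributions may be scalars (shared across
    the three imaging parameters) or per-parameter mappings keyed by
    'volume' / 'suv_mean' / 'suv_max'. All log-scale quantities are base 10.
    """

    n_patients: int
    nodes_per_patient_range: tuple[int, int] = (0, 3)
    baseline_log10_mean_primary: dict | float = 0.3
    baseline_log10_mean_node: dict | float = 0.2
    baseline_log10_sd: dict | float = 0.15
    beta0: dict | float = 0.0
    beta1: dict | float = 0.0
    sigma_b2: dict | float = 0.0
    sigma2: dict | float = 0.005
    retest_sd_log10: dict | float = 0.05
    seed: int = 0
    share_random_intercept: bool = False

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("cohort must contain at least one patient")
        lo, hi = self.nodes_per_patient_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid nodes-per-patient range")
        for name in ("baseline_log10_mean_primary", "baseline_log10_mean_node",
                     "baseline_log10_sd", "beta0", "beta1", "sigma_b2", "sigma2",
                     "retest_sd_log10"):
            setattr(self, name, _as_param_map(getattr(self, name), name))
        if any(v < 0 for v in self.sigma_b2.values()):
            raise ValueError("sigma_b2 must be nonnegative")
        if any(v <= 0 for v in self.sigma2.values()):
            raise ValueError("sigma2 must be strictly positive")
        if any(v < 0 for v in self.retest_sd_log10.values()):
            raise ValueError("retest noise SD must be nonnegative")
        if any(v <= 0 for v in self.baseline_log10_sd.values()):
            raise ValueError("baseline log10 SD must be positive")


def reference_cohort_config(seed: int = 0, n_patients: int | None = None) -> CohortConfig:
    """Default preset emulating the published response cohort: 12 patients,
    one primary plus 0-3 nodes each, baseline moments and per-parameter model
    coefficients from the published fits; test-retest noise set so duplicate
    scans reproduce the published reproducibility-model total variance."""
    mean_p, mean_n, sds = {}, {}, {}
    for p in PARAMETERS:
        mp, sp = presets.BASELINE_MOMENTS_RESPONSE[p]["primary"]
        mn, sn = presets.BASELINE_MOMENTS_RESPONSE[p]["node"]
        mean_p[p], sd_p = lognormal_log10_params(mp, sp)
        mean_n[p], sd_n = lognormal_log10_params(mn, sn)
        sds[p] = 0.5 * (sd_p + sd_n)
    model_b = presets.PUBLISHED_MODEL_B
    model_a = presets.PUBLISHED_MODEL_A
    return CohortConfig(
        n_patients=presets.RESPONSE_COHORT_N_PATIENTS if n_patients is None else n_patients,
        nodes_per_patient_range=(0, 3),
        baseline_log10_mean_primary=mean_p,
        baseline_log10_mean_node=mean_n,
        baseline_log10_sd=sds,
        beta0={p: model_b[p]["beta0"] for p in PARAMETERS},
        beta1={p: model_b[p]["beta1"] for p in PARAMETERS},
        sigma_b2={p: model_b[p]["sigma_b2"] for p in PARAMETERS},
        sigma2={p: model_b[p]["sigma2"] for p in PARAMETERS},
        retest_sd_log10={
            p: math.sqrt((model_a[p]["sigma_b2"] + model_a[p]["sigma2"]) / 2.0)
            for p in PARAMETERS
        },
        seed=seed,
    )


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a tidy cohort table (one row = lesion x scan).

    Columns: patient_id, lesion_id, lesion_type, scan_label (S1/S2/S3),
    volume_cm3, suv_mean, suv_max. Draw order per patient: node count; random
    intercepts (one per parameter, or one shared); then per lesion and
    parameter the baseline truth, two retest noises and the treatment
    residual. Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.nodes_per_patient_range
    rows = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        n_nodes = int(rng.integers(lo, hi + 1))
        if config.share_random_intercept:
            shared_b = float(rng.normal(0.0, 1.0))
            b = {p: shared_b * math.sqrt(config.sigma_b2[p]) for p in PARAMETERS}
        else:
            b = {
                p: float(rng.normal(0.0, math.sqrt(config.sigma_b2[p])))
                for p in PARAMETERS
            }
        lesions = [("L00", "primary")] + [(f"L{k + 1:02d}", "node") for k in range(n_nodes)]
        for lid, ltype in lesions:
            vals = {"S1": {}, "S2": {}, "S3": {}}
            for p in PARAMETERS:
                mean = (
                    config.baseline_log10_mean_primary[p]
                    if ltype == "primary"
                    else config.baseline_log10_mean_node[p]
                )
                base = float(rng.normal(mean, config.baseline_log10_sd[p]))
                e1 = float(rng.normal(0.0, config.retest_sd_log10[p]))
                e2 = float(rng.normal(0.0, config.retest_sd_log10[p]))
                eps = float(rng.normal(0.0, math.sqrt(config.sigma2[p])))
                s1 = base + e1
                s2 = base + e2
                s3 = s2 + config.beta0[p] + b[p] + config.beta1[p] * (ltype == "node") + eps
                vals["S1"][p], vals["S2"][p], vals["S3"][p] = s1, s2, s3
            for scan in ("S1", "S2", "S3"):
                rows.append(
                    {
                        "patient_id": pid,
                        "lesion_id": lid,
                        "lesion_type": ltype,
                        "scan_label": scan,
                        **{_PARAM_COLUMNS[p]: 10.0 ** vals[scan][p] for p in PARAMETERS},
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PhantomSpec:
    """Geometry of a digital uptake phantom.

    Lesion ellipsoids are (center_mm, semi_axes_mm, activity_kbq_ml, type);
    the bone-marrow compartment is an axis-aligned box ((lo_mm, hi_mm),
    activity). Defaults mirror the acquisition protocol's voxel size and
    post-reconstruction smoothing.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: tuple[float, float, float] = presets.SCANNER_VOXEL_SIZE_MM
    lesion_ellipsoids: list = field(default_factory=list)
    background_activity: float = 0.5
    bone_marrow_region: tuple | None = None  # ((lo_mm, hi_mm), activity)
    smoothing_fwhm_mm: float = presets.SCANNER_SMOOTHING_FWHM_MM
    noise_sd: float = 0.0

    def __post_init__(self):
        if any(s <= 0 for s in self.grid_shape) or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("grid shape and voxel size must be positive")
        if self.background_activity < 0 or self.noise_sd < 0 or self.smoothing_fwhm_mm < 0:
            raise ValueError("activities, noise SD and FWHM must be nonnegative")
        for center, axes, activity, ltype in self.lesion_ellipsoids:
            if activity < 0:
                raise ValueError("lesion activity must be nonnegative")
            if any(a <= 0 for a in axes):
                raise ValueError("ellipsoid semi-axes must be positive")
            for c, a, n, v in zip(center, axes, self.grid_shape, self.voxel_size_mm):
                if c - a < 0 or c + a > n * v:
                    raise ValueError("ellipsoid extends outside the grid")
            if ltype not in ("primary", "node"):
                raise ValueError("lesion type must be primary or node")


def _voxel_centers(spec: PhantomSpec):
    grids = [
        (np.arange(n) + 0.5) * v for n, v in zip(spec.grid_shape, spec.voxel_size_mm)
    ]
    return np.meshgrid(*grids, indexing="ij")


def generate_phantom(spec: PhantomSpec, seed: int = 0):
    """Build (activity image kBq/ml, lesion masks, bone mask).

    Masks are ground truth, taken before smoothing/noise. Overlapping lesion
    ellipsoids are an error (ambiguous ground truth); lesions may abut or
    overlap the bone box, which is exactly the contamination scenario the
    bone-overlap QC exists to flag.
    """
    xs, ys, zs = _voxel_centers(spec)
    img = np.full(spec.grid_shape, spec.background_activity, dtype=float)

    bone_mask = np.zeros(spec.grid_shape, dtype=bool)
    if spec.bone_marrow_region is not None:
        (lo, hi), activity = spec.bone_marrow_region
        bone_mask = (
            (xs >= lo[0]) & (xs <= hi[0])
            & (ys >= lo[1]) & (ys <= hi[1])
            & (zs >= lo[2]) & (zs <= hi[2])
        )
        img[bone_mask] = activity

    masks = []
    occupied = np.zeros(spec.grid_shape, dtype=bool)
    for center, axes, activity, ltype in spec.lesion_ellipsoids:
        m = (
            ((xs - center[0]) / axes[0]) ** 2
            + ((ys - center[1]) / axes[1]) ** 2
            + ((zs - center[2]) / axes[2]) ** 2
        ) <= 1.0
        if np.any(m & occupied):
            raise ValueError("overlapping lesion ellipsoids: ground truth is ambiguous")
        occupied |= m
        img[m] = activity
        masks.append({"mask": m, "type": ltype})

    if spec.smoothing_fwhm_mm > 0:
        sigma_vox = [
            spec.smoothing_fwhm_mm / 2.3548200450309493 / v for v in spec.voxel_size_mm
        ]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    return img, masks, bone_mask


def generate_survival(
    cohort: pd.DataFrame,
    link: float,
    baseline_hazard: float,
    censor_rate: float = 0.3,
    seed: int = 0,
    covariate: str = "suv_max",
) -> pd.DataFrame:
    """Exponential survival times with log-hazard linear in a per-patient
    covariate (the primary lesion's on-treatment value).

    hazard_i = baseline_hazard * exp(link * covariate_i); censoring times are
    independent exponentials with rate chosen so roughly ``censor_rate`` of
    records are censored at the baseline hazard; censor_rate = 1 censors
    everything. Columns: patient_id, time_months, event, covariate.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must be a fraction in [0, 1]")
    col = _PARAM_COLUMNS.get(covariate, covariate)
    on_rt = cohort[(cohort.scan_label == "S3") & (cohort.lesion_type == "primary")]
    if on_rt.empty:
        raise ValueError("cohort has no on-treatment primary-lesion values")
    rng = np.random.default_rng(seed)
    rows = []
    for row in on_rt.itertuples():
        cov = float(getattr(row, col))
        hazard = baseline_hazard * math.exp(link * cov)
        t_event = float(rng.exponential(1.0 / hazard))
        if censor_rate >= 1.0:
            rows.append({"patient_id": row.patient_id, "time_months": t_event,
                         "event": False, "covariate": cov})
            continue
        if censor_rate == 0.0:
            rows.append({"patient_id": row.patient_id, "time_months": t_event,
                         "event": True, "covariate": cov})
            continue
        censor_hazard = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_censor = float(rng.exponential(1.0 / censor_hazard))
        rows.append(
            {
                "patient_id": row.patient_id,
                "time_months": min(t_event, t_censor),
                "event": t_event <= t_censor,
                "covariate": cov,
            }
        )
    return pd.DataFrame(rows)
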