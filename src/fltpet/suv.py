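"""SUV quantification: activity-concentration images (kBq/ml) to standardized
uptake value maps, Gaussian smoothing, VOI statistics, and bone-marrow overlap
quality control.

SUV convention: SUV(g/ml) = tissue activity (kBq/ml) x body weight (kg) /
injected dose (MBq). The kBq/MBq factor of 1e-3 cancels against the implicit
tissue density of 1 g/ml and kg/g factor, so 1 kBq/ml at dose/weight of
1 MBq/kg gives SUV 1.0. Decay correction, when the input image is not already
decay-corrected, refers activity back to injection time using the F-18
half-life.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

F18_HALF_LIFE_MIN = 109.77
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # 1 / (2 sqrt(2 ln 2))

__all__ = [
    "F18_HALF_LIFE_MIN",
    "ScanMeta",
    "SUVImage",
    "LesionObservation",
    "BoneOverlapReport",
    "compute_suv_map",
    "smooth_image",
    "extract_voi_stats",
    "check_bone_overlap",
    "load_nifti",
    "save_nifti",
]


@dataclass(frozen=True)
class ScanMeta:
    """Per-scan acquisition facts needed for SUV normalization."""

    patient_id: str
    scan_label: str  # S1 | S2 | S3
    injected_dose_MBq: float
    body_weight_kg: float
    injection_to_frame_min: float = 0.0
    decay_corrected: bool = True

    def __post_init__(self):
        if self.injected_dose_MBq <= 0:
            raise ValueError("injected dose must be strictly positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be strictly positive")
        if self.injection_to_frame_min < 0:
            raise ValueError("injection-to-frame time cannot be negative")
        if self.scan_label not in ("S1", "S2", "S3"):
            raise ValueError("scan_label must be one of S1, S2, S3")

    @classmethod
    def from_json(cls, path) -> "ScanMeta":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SUVImage:
    """SUV parametric map (g/ml) on a regular voxel grid."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("SUV image must be a 3-D grid")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        a, b, c = self.voxel_size_mm
        return a * b * c


@dataclass(frozen=True)
class LesionObservation:
    """Volume, SUV_mean and SUV_max of one lesion on one scan."""

    patient_id: str
    lesion_id: str
    lesion_type: str  # primary | node
    scan_label: str
    volume_cm3: float
    suv_mean: float
    suv_max: float

    def __post_init__(self):
        if self.volume_cm3 <= 0:
            raise ValueError("volume must be positive")
        if not (self.suv_max >= self.suv_mean > 0):
            raise ValueError("require suv_max >= suv_mean > 0")


@dataclass(frozen=True)
class BoneOverlapReport:
    n_violations: int
    margin_voxels: int
    passed: bool


def compute_suv_map(
    activity_kbq_ml: np.ndarray,
    meta: ScanMeta,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    negative_tolerance: float = 0.01,
) -> SUVImage:
    """Convert an activity-concentration image to an SUV map.

    If ``meta.decay_corrected`` is false, activity is first corrected back to
    injection time: A_corr = A * 2^(t / T_half) with T_half = 109.77 min.
    Small negative voxels (reconstruction noise) up to ``negative_tolerance``
    times the image maximum are clamped to zero; larger negatives are an error.
    """
    a = np.asarray(activity_kbq_ml, dtype=float)
    amax = float(a.max()) if a.size else 0.0
    if a.size and float(a.min()) < -negative_tolerance * max(amax, 1e-12):
        raise ValueError("activity image has negative values beyond noise tolerance")
    a = np.clip(a, 0.0, None)
    if not meta.decay_corrected:
        a = a * 2.0 ** (meta.injection_to_frame_min / F18_HALF_LIFE_MIN)
    suv = a * meta.body_weight_kg / meta.injected_dose_MBq
    return SUVImage(values=suv, voxel_size_mm=tuple(voxel_size_mm))


def smooth_image(img: SUVImage, fwhm_mm: float) -> SUVImage:
    """Isotropic Gaussian smoothing of the stated FWHM (mm); fwhm 0 is identity."""
    if fwhm_mm < 0:
        raise ValueError("FWHM cannot be negative")
    if fwhm_mm == 0:
        return SUVImage(values=img.values.copy(), voxel_size_mm=img.voxel_size_mm)
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in img.voxel_size_mm]
    return SUVImage(
        values=ndimage.gaussian_filter(img.values, sigma=sigma_vox),
        voxel_size_mm=img.voxel_size_mm,
    )


def extract_voi_stats(
    img: SUVImage,
    mask: np.ndarray,
    patient_id: str,
    lesion_id: str,
    lesion_type: str,
    scan_label: str,
) -> LesionObservation:
    """VOI statistics: volume (cm3) from voxel count, SUV_mean, SUV_max."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.values.shape:
        raise ValueError("mask shape does not match image shape")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty VOI mask")
    vals = img.values[mask]
    return LesionObservation(
        patient_id=patient_id,
        lesion_id=lesion_id,
        lesion_type=lesion_type,
        scan_label=scan_label,
        volume_cm3=n * img.voxel_volume_mm3 / 1000.0,
        suv_mean=float(vals.mean()),
        suv_max=float(vals.max()),
    )


def check_bone_overlap(
    mask: np.ndarray,
    bone_mask: np.ndarray,
    margin_voxels: int = 0,
    max_allowed: int = 0,
) -> BoneOverlapReport:
    """Count lesion voxels within ``margin_voxels`` (6-connectivity) of bone.

    Bone-marrow signal adjacent to a tumour VOI can contaminate uptake
    statistics, so the delineation protocol requires a margin between VOI and
    skeleton; this check flags any encroachment. Default: zero overlapping
    voxels allowed.
    """
    mask = np.asarray(mask).astype(bool)
    bone_mask = np.asarray(bone_mask).astype(bool)
    if mask.shape != bone_mask.shape:
        raise ValueError("mask shapes differ")
    if margin_voxels < 0:
        raise ValueError("margin cannot be negative")
    zone = bone_mask
    if margin_voxels > 0:
        structure = ndimage.generate_binary_structure(mask.ndim, 1)
        zone = ndimage.binary_dilation(bone_mask, structure=structure, iterations=margin_voxels)
    n = int(np.count_nonzero(mask & zone))
    return BoneOverlapReport(n_violations=n, margin_voxels=margin_voxels, passed=n <= max_allowed)


def save_nifti(values: np.ndarray, voxel_size_mm, path) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=float), zooms
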