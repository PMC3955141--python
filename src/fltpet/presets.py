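"""Published summary statistics for the NSCLC radiotherapy FLT PET cohort.

These constants parameterize the default synthetic cohort and serve as the
reference point for the analytic identities (back-transformed effect sizes,
variance partitions, repeatability coefficients) that the package recomputes.
All values are log10-scale mixed-model estimates or natural-scale summary
moments reported for a cohort of 16 NSCLC patients imaged with
[18F]fluorothymidine PET before and during radical radiotherapy
(7 patients / 18 lesions evaluable for test-retest reproducibility,
12 patients / 30 lesions evaluable for response).
"""

from __future__ import annotations

PARAMETERS = ("volume", "suv_mean", "suv_max")

# Offset-ANCOVA estimates on duplicate baseline scans (reproducibility model).
# beta0: systematic retest shift for primaries; beta1: node - primary contrast;
# sigma_b2 / sigma2: cross-patient and residual variance (log10 scale).
PUBLISHED_MODEL_A = {
    "suv_mean": {"beta0": -0.014, "beta1": 0.015, "sigma_b2": 0.00000, "sigma2": 0.00448},
    "suv_max": {"beta0": 0.024, "beta1": -0.025, "sigma_b2": 0.00188, "sigma2": 0.00291},
    "volume": {"beta0": 0.041, "beta1": -0.025, "sigma_b2": 0.00300, "sigma2": 0.00374},
}

# Offset-ANCOVA estimates on baseline -> on-treatment scans (response model).
PUBLISHED_MODEL_B = {
    "suv_mean": {"beta0": -0.127, "beta1": -0.095, "sigma_b2": 0.00224, "sigma2": 0.00556},
    "suv_max": {"beta0": -0.119, "beta1": -0.147, "sigma_b2": 0.00154, "sigma2": 0.00839},
    "volume": {"beta0": 0.018, "beta1": -0.177, "sigma_b2": 0.00858, "sigma2": 0.05579},
}

# SD of percentage test-retest differences across lesions (the quantity whose
# 1.96-multiple is the repeatability coefficient), and the mean bias, percent.
PUBLISHED_TEST_RETEST_SD = {
    "volume": {"primaries": 12.8, "nodes": 22.5, "all": 18.9},
    "suv_mean": {"primaries": 8.9, "nodes": 18.0, "all": 14.9},
    "suv_max": {"primaries": 12.6, "nodes": 17.2, "all": 15.3},
}
PUBLISHED_TEST_RETEST_MEAN = {
    "volume": {"primaries": 9.5, "nodes": 8.4, "all": 8.8},
    "suv_mean": {"primaries": -2.9, "nodes": 0.6, "all": -0.8},
    "suv_max": {"primaries": 5.7, "nodes": 3.1, "all": 4.1},
}

# Natural-scale baseline moments (mean, SD) of the response cohort, by lesion
# type: lesion volume in cm3, SUV_mean and SUV_max in g/ml.
BASELINE_MOMENTS_RESPONSE = {
    "volume": {"primary": (78.0, 56.0), "node": (7.4, 5.3)},
    "suv_mean": {"primary": (2.2, 0.7), "node": (1.7, 0.4)},
    "suv_max": {"primary": (5.3, 2.0), "node": (3.2, 0.9)},
}

# Scanner geometry: reconstruction grid and post-reconstruction smoothing of
# the Biograph 6 TruePoint TrueV protocol used to acquire the cohort.
SCANNER_VOXEL_SIZE_MM = (2.67, 2.67, 2.00)
SCANNER_GRID_SHAPE = (256, 256, 109)
SCANNER_SMOOTHING_FWHM_MM = 4.0

# Cohort accounting: response cohort size used by the default preset.
RESPONSE_COHORT_N_PATIENTS = 12
RESPONSE_COHORT_N_PRIMARIES = 12
RESPONSE_COHORT_N_NODES = 18
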