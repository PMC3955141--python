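"""Synthetic cohort, phantom and survival generators: the statistical
structure the downstream analyses assume must hold by construction."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from fltpet.suv import ScanMeta, SUVImage, check_bone_overlap, compute_suv_map, extract_voi_stats
from fltpet.synthetic import (
    CohortConfig,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
    generate_survival,
    lognormal_log10_params,
    reference_cohort_config,
)
from fltpet.outcome import cox_univariate


def _log_ratio(cohort, param_col, lesion_type=None):
    wide = cohort.pivot_table(
        index=["patient_id", "lesion_id", "lesion_type"],
        columns="scan_label",
        values=param_col,
    ).reset_index()
    if lesion_type:
        wide = wide[wide.lesion_type == lesion_type]
    return np.log10(wide["S3"] / wide["S2"]).values


class TestGenerateCohort:
    def test_zero_retest_noise_gives_identical_baselines(self):
        cfg = CohortConfig(n_patients=5, retest_sd_log10=0.0, seed=3)
        co = generate_cohort(cfg)
        s1 = co[co.scan_label == "S1"].sort_values(["patient_id", "lesion_id"])
        s2 = co[co.scan_label == "S2"].sort_values(["patient_id", "lesion_id"])
        for col in ("volume_cm3", "suv_mean", "suv_max"):
            np.testing.assert_allclose(s1[col].values, s2[col].values, rtol=1e-12)

    def test_null_model_symmetry(self):
        cfg = CohortConfig(
            n_patients=400, beta0=0.0, beta1=0.0, sigma_b2=0.0, sigma2=0.004, seed=4
        )
        z = _log_ratio(generate_cohort(cfg), "suv_mean")
        assert abs(z.mean()) < 3 * z.std(ddof=1) / math.sqrt(z.size)

    def test_node_effect_matches_closed_form(self):
        """At the published response-model SUV_mean parameters the geometric
        mean node effect converges to 10^(beta0+beta1) - 1 ~ -40%."""
        cfg = CohortConfig(
            n_patients=500,
            beta0=-0.127,
            beta1=-0.095,
            sigma_b2=0.00224,
            sigma2=0.00556,
            seed=5,
        )
        z = _log_ratio(generate_cohort(cfg), "suv_mean", lesion_type="node")
        effect = (10.0 ** z.mean() - 1.0) * 100.0
        expected = (10.0 ** (-0.222) - 1.0) * 100.0
        assert effect == pytest.approx(expected, abs=2.0)

    def test_fixed_seed_is_bit_reproducible(self):
        cfg = reference_cohort_config(seed=9)
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_all_values_strictly_positive(self, reference_cohort):
        for col in ("volume_cm3", "suv_mean", "suv_max"):
            assert (reference_cohort[col] > 0).all()

    def test_patient_mean_residual_variance(self):
        """Var of patient-mean residuals converges to sigma_b^2 + sigma^2/m
        for m lesions per patient."""
        sb2, s2, m = 0.004, 0.006, 3
        cfg = CohortConfig(
            n_patients=3000,
            nodes_per_patient_range=(m - 1, m - 1),
            beta0=-0.1,
            beta1=-0.05,
            sigma_b2=sb2,
            sigma2=s2,
            seed=6,
        )
        co = generate_cohort(cfg)
        wide = co.pivot_table(
            index=["patient_id", "lesion_id", "lesion_type"],
            columns="scan_label",
            values="suv_mean",
        ).reset_index()
        z = np.log10(wide["S3"] / wide["S2"]).values
        resid = z - (-0.1) - (-0.05) * (wide.lesion_type == "node").values
        means = pd.Series(resid).groupby(wide.patient_id.values).mean()
        assert means.var(ddof=1) == pytest.approx(sb2 + s2 / m, rel=0.12)

    def test_log_ratios_are_gaussian(self):
        cfg = CohortConfig(n_patients=150, beta0=-0.1, sigma_b2=0.0, sigma2=0.005, seed=8)
        z = _log_ratio(generate_cohort(cfg), "suv_max")
        assert sps.shapiro(z).pvalue > 0.01

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=0)
        with pytest.raises(ValueError):
            CohortConfig(n_patients=3, sigma2=0.0)
        with pytest.raises(ValueError):
            CohortConfig(n_patients=3, nodes_per_patient_range=(-1, 2))

    def test_reference_preset_matches_published_baseline_moments(self):
        """Lognormal moment matching: large-cohort natural-scale means should
        approach the published baseline summary (e.g. primary SUV_mean 2.2)."""
        cfg = reference_cohort_config(seed=10, n_patients=2000)
        co = generate_cohort(cfg)
        s1 = co[(co.scan_label == "S1") & (co.lesion_type == "primary")]
        assert s1.suv_mean.mean() == pytest.approx(2.2, rel=0.05)
        assert s1.volume_cm3.mean() == pytest.approx(78.0, rel=0.08)

    def test_lognormal_moment_matching_roundtrip(self):
        mu10, sd10 = lognormal_log10_params(2.2, 0.7)
        rng = np.random.default_rng(0)
        x = 10.0 ** rng.normal(mu10, sd10, 200_000)
        assert x.mean() == pytest.approx(2.2, rel=0.01)
        assert x.std() == pytest.approx(0.7, rel=0.03)


class TestGeneratePhantom:
    def test_noise_free_unsmoothed_lesion_quantifies_exactly(self):
        spec = PhantomSpec(
            grid_shape=(40, 40, 40),
            voxel_size_mm=(2.0, 2.0, 2.0),
            lesion_ellipsoids=[((40.0, 40.0, 40.0), (10.0, 10.0, 10.0), 5.0, "primary")],
            background_activity=1.0,
            smoothing_fwhm_mm=0.0,
            noise_sd=0.0,
        )
        img, masks, _ = generate_phantom(spec)
        meta = ScanMeta("P", "S1", injected_dose_MBq=350.0, body_weight_kg=70.0)
        suv = compute_suv_map(img, meta, voxel_size_mm=spec.voxel_size_mm)
        obs = extract_voi_stats(suv, masks[0]["mask"], "P", "L0", "primary", "S1")
        assert obs.suv_mean == pytest.approx(5.0 * 70.0 / 350.0, rel=1e-12)
        assert obs.suv_max == pytest.approx(obs.suv_mean, rel=1e-12)

    def test_sphere_mask_volume_matches_voxelized_count(self):
        r = 10.0
        spec = PhantomSpec(
            grid_shape=(40, 40, 40),
            voxel_size_mm=(2.0, 2.0, 2.0),
            lesion_ellipsoids=[((40.0, 40.0, 40.0), (r, r, r), 5.0, "primary")],
            smoothing_fwhm_mm=0.0,
        )
        _, masks, _ = generate_phantom(spec)
        count = int(masks[0]["mask"].sum())
        # independent voxel-center count oracle
        centers = (np.arange(40) + 0.5) * 2.0
        xs, ys, zs = np.meshgrid(centers, centers, centers, indexing="ij")
        oracle = int(
            (((xs - 40) ** 2 + (ys - 40) ** 2 + (zs - 40) ** 2) <= r**2).sum()
        )
        assert count == oracle
        analytic = 4.0 / 3.0 * math.pi * r**3
        shell = 4.0 * math.pi * r**2 * 2.0  # one-voxel-thick surface shell
        assert abs(count * 8.0 - analytic) < shell

    def test_overlapping_lesions_rejected(self):
        spec = PhantomSpec(
            grid_shape=(30, 30, 30),
            voxel_size_mm=(2.0, 2.0, 2.0),
            lesion_ellipsoids=[
                ((30.0, 30.0, 30.0), (8.0, 8.0, 8.0), 5.0, "primary"),
                ((34.0, 30.0, 30.0), (8.0, 8.0, 8.0), 4.0, "node"),
            ],
        )
        with pytest.raises(ValueError):
            generate_phantom(spec)

    def test_bone_adjacent_lesion_is_flagged(self):
        spec = PhantomSpec(
            grid_shape=(30, 30, 30),
            voxel_size_mm=(2.0, 2.0, 2.0),
            lesion_ellipsoids=[((30.0, 30.0, 30.0), (8.0, 8.0, 8.0), 5.0, "primary")],
            bone_marrow_region=(((20.0, 20.0, 20.0), (40.0, 40.0, 40.0)), 3.0),
            smoothing_fwhm_mm=0.0,
        )
        _, masks, bone = generate_phantom(spec)
        rep = check_bone_overlap(masks[0]["mask"], bone)
        assert rep.n_violations > 0 and not rep.passed

    def test_ellipsoid_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(
                grid_shape=(10, 10, 10),
                voxel_size_mm=(2.0, 2.0, 2.0),
                lesion_ellipsoids=[((1.0, 10.0, 10.0), (5.0, 5.0, 5.0), 1.0, "primary")],
            )


class TestGenerateSurvival:
    def _cohort(self, n, seed=0):
        return generate_cohort(
            reference_cohort_config(seed=seed, n_patients=n)
        )

    def test_null_link_gives_unit_hazard_ratio(self):
        surv = generate_survival(self._cohort(1500, seed=1), link=0.0,
                                 baseline_hazard=0.05, censor_rate=0.2, seed=2)
        fit = cox_univariate(surv.time_months, surv.event, surv.covariate)
        assert fit.ci95[0] < 1.0 < fit.ci95[1]

    def test_recovers_true_hazard_ratio(self):
        surv = generate_survival(self._cohort(2000, seed=3), link=math.log(2.0),
                                 baseline_hazard=0.05, censor_rate=0.2, seed=4)
        fit = cox_univariate(surv.time_months, surv.event, surv.covariate)
        assert fit.ci95[0] < 2.0 < fit.ci95[1]
        assert fit.hr == pytest.approx(2.0, rel=0.15)

    def test_full_censoring_breaks_cox(self):
        surv = generate_survival(self._cohort(30, seed=5), link=0.0,
                                 baseline_hazard=0.05, censor_rate=1.0, seed=6)
        assert not surv.event.any()
        with pytest.raises(ValueError):
            cox_univariate(surv.time_months, surv.event, surv.covariate)

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError):
            generate_survival(self._cohort(5), link=0.0, baseline_hazard=-1.0)
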