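"""Random-intercept offset ANCOVA: profile-ML fit vs grid-search oracle,
statsmodels cross-check, back-transformation and variance partition."""

import math

import numpy as np
import pytest

from fltpet.mixed_model import (
    back_transform_effect,
    effect_ci,
    fit_ancova,
    fit_ancova_with_covariate,
    variance_partition,
)


def _oracle_loglik(lam, sigma2, z, X, pats):
    """Full-matrix marginal log-likelihood with GLS beta: built independently
    of the package internals (explicit V, slogdet, solve)."""
    n = z.size
    _, codes = np.unique(pats, return_inverse=True)
    ZZt = (codes[:, None] == codes[None, :]).astype(float)
    V = sigma2 * (np.eye(n) + lam * ZZt)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ z)
    r = z - X @ beta
    _, logdet = np.linalg.slogdet(V)
    return -0.5 * (n * math.log(2 * math.pi) + logdet + float(r @ Vi @ r))


def _tiny_fixture():
    rng = np.random.default_rng(21)
    pats = np.array([0, 0, 1, 1, 2, 2])
    nodes = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
    b = rng.normal(0, 0.08, 3)[pats]
    z = -0.1 - 0.08 * nodes + b + rng.normal(0, 0.07, 6)
    y0 = 10 ** rng.normal(0.3, 0.2, 6)
    return y0, y0 * 10**z, pats, nodes


class TestFitAncova:
    def test_profile_optimum_beats_dense_grid(self):
        """On a tiny fixture the profile-ML optimum must dominate a 50x50
        (lambda, sigma^2) grid with GLS fixed effects, to 1e-6."""
        y0, y1, pats, nodes = _tiny_fixture()
        fit = fit_ancova(y0, y1, pats, nodes)
        z = np.log10(y1 / y0)
        X = np.column_stack([np.ones_like(z), nodes])
        best = -np.inf
        for lam in np.linspace(0.0, 8.0, 50):
            for s2 in np.geomspace(fit.sigma2 / 10, fit.sigma2 * 10, 50):
                best = max(best, _oracle_loglik(lam, s2, z, X, pats))
        assert fit.loglik >= best - 1e-6

    def test_matches_statsmodels_mixedlm(self, mixed_fixture):
        sm = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        y0, y1, pats, nodes = mixed_fixture
        fit = fit_ancova(y0, y1, pats, nodes)
        z = np.log10(y1 / y0)
        X = np.column_stack([np.ones_like(z), nodes])
        ref = sm.MixedLM(z, X, groups=pats).fit(reml=False)
        np.testing.assert_allclose(fit.beta, np.asarray(ref.fe_params), atol=1e-4)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-5)
        assert fit.sigma2 == pytest.approx(ref.scale, abs=1e-5)
        assert fit.sigma_b2 == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), abs=1e-5)
        np.testing.assert_allclose(fit.se, np.asarray(ref.bse_fe), atol=1e-5)

    def test_degenerate_random_effect_recovered(self):
        rng = np.random.default_rng(33)
        n_pat, m = 120, 3
        pats = np.repeat(np.arange(n_pat), m)
        nodes = (np.arange(n_pat * m) % 2).astype(float)
        z = -0.12 - 0.09 * nodes + rng.normal(0, 0.075, n_pat * m)
        y0 = 10 ** rng.normal(0.3, 0.15, n_pat * m)
        fit = fit_ancova(y0, y0 * 10**z, pats, nodes)
        assert fit.beta0 == pytest.approx(-0.12, abs=0.015)
        assert fit.beta1 == pytest.approx(-0.09, abs=0.015)
        assert fit.sigma_b2 < 5e-4  # lambda at or near the zero boundary

    def test_scale_invariance(self, mixed_fixture):
        y0, y1, pats, nodes = mixed_fixture
        a = fit_ancova(y0, y1, pats, nodes)
        b = fit_ancova(7.3 * y0, 7.3 * y1, pats, nodes)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-10)
        assert a.sigma2 == pytest.approx(b.sigma2, rel=1e-8)
        assert a.sigma_b2 == pytest.approx(b.sigma_b2, rel=1e-6)

    def test_aic_counts_four_parameters(self, mixed_fixture):
        y0, y1, pats, nodes = mixed_fixture
        fit = fit_ancova(y0, y1, pats, nodes)
        assert fit.aic == pytest.approx(-2.0 * fit.loglik + 2.0 * 4)

    def test_single_lesion_type_drops_contrast(self, mixed_fixture):
        y0, y1, pats, nodes = mixed_fixture
        fit = fit_ancova(y0, y1, pats, np.zeros_like(nodes))
        assert fit.beta1 is None
        assert any("node" in w for w in fit.warnings)

    def test_input_validation(self, mixed_fixture):
        y0, y1, pats, nodes = mixed_fixture
        with pytest.raises(ValueError):
            fit_ancova(-y0, y1, pats, nodes)
        with pytest.raises(ValueError):
            fit_ancova(y0, y1, np.zeros_like(pats), nodes)  # single patient

    def test_deterministic_refits(self, mixed_fixture):
        y0, y1, pats, nodes = mixed_fixture
        a = fit_ancova(y0, y1, pats, nodes)
        b = fit_ancova(y0, y1, pats, nodes)
        assert a.loglik == b.loglik and np.array_equal(a.beta, b.beta)


class TestCovariateExtension:
    def _simulate(self, seed, beta2=0.0, n_pat=40):
        rng = np.random.default_rng(seed)
        m = 3
        pats = np.repeat(np.arange(n_pat), m)
        nodes = (np.arange(n_pat * m) % 2).astype(float)
        cov = np.repeat(rng.uniform(30, 70, n_pat), m)
        b = rng.normal(0, 0.05, n_pat)[pats]
        z = -0.1 - 0.08 * nodes + beta2 * cov + b + rng.normal(0, 0.07, n_pat * m)
        y0 = 10 ** rng.normal(0.3, 0.2, n_pat * m)
        return y0, y0 * 10**z, pats, nodes, cov

    def test_null_covariate_does_not_improve_fit_on_average(self):
        daics = []
        for seed in range(20):
            y0, y1, pats, nodes, cov = self._simulate(seed, beta2=0.0)
            _, _, daic = fit_ancova_with_covariate(y0, y1, pats, nodes, cov)
            daics.append(daic)
        assert np.mean(daics) > -1.0  # adding a useless parameter costs AIC

    def test_strong_covariate_improves_fit(self):
        y0, y1, pats, nodes, cov = self._simulate(99, beta2=0.01, n_pat=80)
        _, ext, daic = fit_ancova_with_covariate(y0, y1, pats, nodes, cov)
        assert daic < 0
        assert ext.aic == pytest.approx(-2.0 * ext.loglik + 2.0 * 5)

    def test_constant_covariate_flagged(self, mixed_fixture):
        y0, y1, pats, nodes = mixed_fixture
        base, ext, daic = fit_ancova_with_covariate(
            y0, y1, pats, nodes, np.full(y0.size, 55.0)
        )
        assert ext is None and daic is None
        assert any("constant" in w for w in base.warnings)


class TestBackTransform:
    @pytest.mark.parametrize(
        "beta,expected_pct,rounded",
        [
            (-0.127, -25.35, 25),  # primary SUV_mean effect
            (0.0, 0.0, 0),
            (-0.266, -45.77, 46),  # node SUV_max effect (beta0 + beta1)
        ],
    )
    def test_effect_sizes(self, beta, expected_pct, rounded):
        pct = back_transform_effect(beta)
        assert pct == pytest.approx(expected_pct, abs=0.05)
        assert round(abs(pct)) == rounded

    def test_ci_endpointwise(self):
        lo, hi = effect_ci(-0.127, 0.025)
        z = 1.959963984540054
        assert lo == pytest.approx((10 ** (-0.127 - z * 0.025) - 1) * 100, abs=1e-9)
        assert hi == pytest.approx((10 ** (-0.127 + z * 0.025) - 1) * 100, abs=1e-9)
        assert lo == pytest.approx(-33.27, abs=0.05)
        assert hi == pytest.approx(-16.44, abs=0.05)

    def test_zero_se_collapses(self):
        lo, hi = effect_ci(-0.1, 0.0)
        assert lo == hi == pytest.approx(back_transform_effect(-0.1))

    def test_asymmetry_after_back_transform(self):
        # 10^x is convex: a log-symmetric interval is natural-scale asymmetric
        beta, se = -0.2, 0.05
        lo, hi = effect_ci(beta, se)
        point = back_transform_effect(beta)
        assert hi - point > point - lo

    def test_t_interval_wider_than_normal(self):
        lo_n, hi_n = effect_ci(-0.127, 0.025, ci_method="normal")
        lo_t, hi_t = effect_ci(-0.127, 0.025, ci_method="t", df=28)
        assert lo_t < lo_n and hi_t > hi_n


class TestVariancePartition:
    def test_published_components(self):
        assert variance_partition(0.00224, 0.00556) == pytest.approx(0.28718, abs=1e-5)

    def test_edge_cases(self):
        assert variance_partition(0.0, 0.3) == 0.0
        assert variance_partition(0.4, 0.4) == 0.5
        with pytest.raises(ValueError):
            variance_partition(0.0, 0.0)
        with pytest.raises(ValueError):
            variance_partition(-0.1, 0.2)
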