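"""Random-intercept offset ANCOVA on log10-transformed imaging parameters.

Model: log10(y1_ij) = log10(y0_ij) + (beta0 + b_i) + beta1 * x1_ij + eps_ij,
with patient random intercept b_i ~ N(0, sigma_b^2) and lesion-level error
eps_ij ~ N(0, sigma^2). Because the baseline log-value enters with its
coefficient fixed at 1 (an offset), fitting reduces to regressing
z_ij = log10(y1_ij / y0_ij) on an intercept and the node indicator (plus an
optional continuous covariate such as BED), with the random intercept.

Estimation is maximum likelihood by profiling: for a fixed variance ratio
lambda = sigma_b^2 / sigma^2 the GLS estimates of the fixed effects and the
residual scale are closed-form, leaving a 1-D profile log-likelihood in
lambda that is maximized by a deterministic bounded search over lambda >= 0.
ML (not REML) is the default so the AIC of the four-parameter model
(beta0, beta1, sigma_b^2, sigma^2) is well defined; an REML criterion is
available for variance-component reporting.

Effect sizes are back-transformed to percent change: 10^beta0 - 1 for
primaries and 10^(beta0 + beta1) - 1 for nodes, with Wald confidence
intervals computed on the log10 scale and back-transformed endpoint-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm as _norm
from scipy.stats import t as _t_dist

_LOG2PI = math.log(2.0 * math.pi)
Z975 = 1.959963984540054

__all__ = [
    "MixedModelFit",
    "fit_ancova",
    "fit_ancova_with_covariate",
    "back_transform_effect",
    "effect_ci",
    "variance_partition",
    "profile_loglik",
]


@dataclass
class MixedModelFit:
    beta: np.ndarray  # fixed effects: intercept, node indicator, [covariate]
    se: np.ndarray
    p_values: np.ndarray
    cov_beta: np.ndarray
    term_names: list
    sigma_b2: float
    sigma2: float
    loglik: float
    aic: float
    n_patients: int
    n_lesions: int
    converged: bool
    boundary: bool  # lambda pinned at zero
    method: str  # ml | reml
    ci_method: str  # normal | t
    effect_primary_pct: float | None = None
    effect_primary_ci: tuple | None = None
    effect_node_pct: float | None = None
    effect_node_ci: tuple | None = None
    variance_partition: float = 0.0
    warnings: list = field(default_factory=list)

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    @property
    def beta1(self) -> float | None:
        return float(self.beta[1]) if "node" in self.term_names else None


def back_transform_effect(beta: float) -> float:
    """Log10-scale coefficient to percent change: (10^beta - 1) * 100."""
    return (10.0**beta - 1.0) * 100.0


def effect_ci(beta: float, se: float, ci_method: str = "normal", df: int | None = None):
    """95% CI of the back-transformed effect, endpoint-wise on the log scale."""
    if se < 0:
        raise ValueError("standard error cannot be negative")
    if ci_method == "normal":
        crit = Z975
    elif ci_method == "t":
        if df is None or df < 1:
            raise ValueError("t intervals require positive degrees of freedom")
        crit = float(_t_dist.ppf(0.975, df))
    else:
        raise ValueError("ci_method must be 'normal' or 't'")
    lo = back_transform_effect(beta - crit * se)
    hi = back_transform_effect(beta + crit * se)
    return (lo, hi)


def variance_partition(sigma_b2: float, sigma2: float) -> float:
    """Fraction of residual variation due to patient heterogeneity:
    sigma_b^2 / (sigma^2 + sigma_b^2)."""
    if sigma_b2 < 0 or sigma2 < 0:
        raise ValueError("variance components cannot be negative")
    total = sigma_b2 + sigma2
    if total == 0:
        raise ValueError("both variance components are zero")
    return sigma_b2 / total


def _group_codes(patient):
    patient = np.asarray(patient)
    _, codes = np.unique(patient, return_inverse=True)
    return codes, int(codes.max()) + 1


def _gls_at_lambda(lam, z, X, codes, sizes, n_groups):
    """GLS quantities for V0 = I + lam * Z Z' (block-diagonal per patient).

    Uses the Sherman-Morrison form per block:
    (I + lam J_m)^(-1) = I - lam/(1 + lam m) J_m.
    Returns (beta, A = X'V0^-1 X, rVr = r'V0^-1 r, logdet V0).
    """
    n, p = X.shape
    w = lam / (1.0 + lam * sizes)  # per-group shrink weight
    GX = np.zeros((n_groups, p))
    np.add.at(GX, codes, X)
    Gz = np.zeros(n_groups)
    np.add.at(Gz, codes, z)
    A = X.T @ X - (GX * w[:, None]).T @ GX
    c = X.T @ z - (GX * w[:, None]).T @ Gz
    beta = np.linalg.solve(A, c)
    r = z - X @ beta
    Gr = np.zeros(n_groups)
    np.add.at(Gr, codes, r)
    rVr = float(r @ r - w @ (Gr * Gr))
    logdet = float(np.log1p(lam * sizes).sum())
    return beta, A, rVr, logdet


def profile_loglik(lam, z, X, codes, sizes, n_groups, method="ml"):
    """Profile log-likelihood in lambda (sigma^2 and beta profiled out)."""
    n, p = X.shape
    _, A, rVr, logdet = _gls_at_lambda(lam, z, X, codes, sizes, n_groups)
    if method == "ml":
        sigma2 = rVr / n
        return -0.5 * (n * (_LOG2PI + 1.0) + n * math.log(sigma2) + logdet)
    if method == "reml":
        sigma2 = rVr / (n - p)
        sign, logdetA = np.linalg.slogdet(A)
        return -0.5 * (
            (n - p) * (_LOG2PI + 1.0) + (n - p) * math.log(sigma2) + logdet + logdetA
        )
    raise ValueError("method must be 'ml' or 'reml'")


def _fit_core(z, X, codes, sizes, n_groups, method):
    """Maximize the profile likelihood over lambda >= 0 deterministically."""
    grid = np.concatenate([[0.0], np.logspace(-6, 4, 101)])
    lls = np.array([profile_loglik(l, z, X, codes, sizes, n_groups, method) for l in grid])
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda l: -profile_loglik(l, z, X, codes, sizes, n_groups, method),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        lam = float(res.x)
        if profile_loglik(lam, z, X, codes, sizes, n_groups, method) < lls[k]:
            lam = float(grid[k])
    else:
        lam = float(grid[k])
    if profile_loglik(0.0, z, X, codes, sizes, n_groups, method) >= profile_loglik(
        lam, z, X, codes, sizes, n_groups, method
    ) - 1e-12:
        lam = 0.0
    return lam


def fit_ancova(
    y0,
    y1,
    patient,
    node,
    covariate=None,
    method: str = "ml",
    ci_method: str = "normal",
) -> MixedModelFit:
    """Fit the random-intercept offset ANCOVA to paired lesion values.

    Parameters
    ----------
    y0, y1 : positive arrays — pre and post values per lesion (natural scale).
    patient : patient identifier per lesion (grouping for the random intercept).
    node : 0/1 indicator per lesion (1 = nodal lesion). If only one lesion
        type is present the contrast term is dropped with a warning.
    covariate : optional continuous fixed-effect covariate (e.g. BED, Gy).
    method : "ml" (default; AIC-compatible) or "reml".
    ci_method : "normal" (Wald z) or "t" (Wald with n_lesions - 2 df).
    """
    y0 = np.asarray(y0, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    node = np.asarray(node, dtype=float)
    if np.any(y0 <= 0) or np.any(y1 <= 0):
        raise ValueError("y values must be strictly positive (log-transformable)")
    if not (y0.shape == y1.shape == node.shape):
        raise ValueError("y0, y1 and node must have equal length")
    z = np.log10(y1 / y0)
    n = z.size
    codes, n_groups = _group_codes(patient)
    if n_groups < 2:
        raise ValueError("need at least 2 patients")

    warnings_list: list[str] = []
    cols = [np.ones(n)]
    names = ["intercept"]
    if np.unique(node).size > 1:
        cols.append(node)
        names.append("node")
    else:
        warnings_list.append("only one lesion type present; node contrast dropped")
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.shape != z.shape:
            raise ValueError("covariate length mismatch")
        if np.unique(cov).size < 2:
            raise ValueError("constant covariate is collinear with the intercept")
        cols.append(cov)
        names.append("covariate")
    X = np.column_stack(cols)
    p = X.shape[1]

    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    if not np.any(sizes > 1):
        warnings_list.append(
            "no patient has multiple lesions; sigma_b^2 is not identifiable"
        )

    lam = _fit_core(z, X, codes, sizes, n_groups, method)
    beta, A, rVr, logdet = _gls_at_lambda(lam, z, X, codes, sizes, n_groups)
    dof = n if method == "ml" else n - p
    sigma2 = rVr / dof
    sigma_b2 = lam * sigma2
    ll = profile_loglik(lam, z, X, codes, sizes, n_groups, method)
    k = p + 2  # fixed effects + two variance components
    aic = -2.0 * ll + 2.0 * k

    cov_beta = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))
    if ci_method == "t":
        df = max(n - 2, 1)
        pvals = 2.0 * _t_dist.sf(np.abs(beta / se), df)
    else:
        df = None
        pvals = 2.0 * _norm.sf(np.abs(beta / se))

    fit = MixedModelFit(
        beta=beta,
        se=se,
        p_values=pvals,
        cov_beta=cov_beta,
        term_names=names,
        sigma_b2=sigma_b2,
        sigma2=sigma2,
        loglik=ll,
        aic=aic,
        n_patients=n_groups,
        n_lesions=n,
        converged=True,
        boundary=(lam == 0.0),
        method=method,
        ci_method=ci_method,
        warnings=warnings_list,
    )
    fit.variance_partition = variance_partition(sigma_b2, sigma2) if sigma_b2 + sigma2 > 0 else 0.0
    fit.effect_primary_pct = back_transform_effect(fit.beta0)
    fit.effect_primary_ci = effect_ci(fit.beta0, float(se[0]), ci_method, df)
    if "node" in names:
        i = names.index("node")
        b_node = float(beta[0] + beta[i])
        se_node = math.sqrt(cov_beta[0, 0] + cov_beta[i, i] + 2.0 * cov_beta[0, i])
        fit.effect_node_pct = back_transform_effect(b_node)
        fit.effect_node_ci = effect_ci(b_node, se_node, ci_method, df)
    return fit


def fit_ancova_with_covariate(
    y0, y1, patient, node, covariate, method: str = "ml", ci_method: str = "normal"
):
    """Fit the base model and the extension with a continuous covariate.

    Returns (base_fit, extended_fit_or_None, delta_aic). A constant covariate
    cannot be separated from the intercept: the base model is returned with a
    warning and delta_aic = None.
    """
    base = fit_ancova(y0, y1, patient, node, method=method, ci_method=ci_method)
    cov = np.asarray(covariate, dtype=float)
    if np.unique(cov).size < 2:
        base.warnings.append("covariate is constant; extended model skipped")
        return base, None, None
    ext = fit_ancova(y0, y1, patient, node, covariate=cov, method=method, ci_method=ci_method)
    return base, ext, ext.aic - base.aic
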