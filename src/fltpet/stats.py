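"""Self-contained non-parametric statistics: Spearman rank correlation and the
Wilcoxon rank-sum test, with average-rank tie handling.

Both statistics are computed from ranks authored here; scipy is used only for
distribution tail probabilities (Student t, standard normal). Exact reference
p-values are available for small samples: full permutation enumeration for
Spearman (n <= 10) and the exact rank-sum null distribution (n1 + n2 <= 20,
no ties) obtained by dynamic programming over rank subsets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm as _norm
from scipy.stats import t as _t_dist

__all__ = [
    "CorrelationResult",
    "RankTestResult",
    "average_ranks",
    "spearman",
    "wilcoxon_rank_sum",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_two_sided: float
    n: int
    method: str = "t_approx"


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_two_sided: float
    n1: int
    n2: int
    method: str


def average_ranks(x) -> np.ndarray:
    """Midranks: tied values share the average of the ranks they occupy."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sorted_x = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if denom == 0.0:
        raise ValueError("constant input: Spearman rho is undefined")
    return float(rxc @ ryc) / denom


def spearman(x, y, method: str = "t_approx") -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    method="t_approx" (default): p from t = rho*sqrt((n-2)/(1-rho^2)) on n-2
    degrees of freedom. method="exact": full enumeration of the n! rank
    permutations (n <= 10), p = fraction of permutations with |rho| at least
    as large as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 observations")
    rx, ry = average_ranks(x), average_ranks(y)
    rho = _rank_corr(rx, ry)

    if method == "t_approx":
        if abs(rho) >= 1.0:
            p = 0.0 if n > 2 else 1.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(_t_dist.sf(abs(t), n - 2))
        return CorrelationResult(rho=rho, p_two_sided=min(p, 1.0), n=n, method=method)

    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p only offered for n <= 10")
        # |rho| is monotone in |sum(rxc * ry_perm) - const|, but with ties the
        # scale is fixed, so compare |rho| directly; vectorize over chunks.
        rxc = rx - rx.mean()
        sx = math.sqrt(float(rxc @ rxc))
        ryc = ry - ry.mean()
        sy = math.sqrt(float(ryc @ ryc))
        obs = abs(rho) - 1e-12
        count = 0
        total = 0
        chunk: list[tuple] = []

        def _flush(chunk):
            arr = np.array(chunk, dtype=float)
            rhos = (arr @ rxc) / (sx * sy)
            return int(np.count_nonzero(np.abs(rhos) >= obs))

        for perm in itertools.permutations(ryc.tolist()):
            chunk.append(perm)
            total += 1
            if len(chunk) == 50000:
                count += _flush(chunk)
                chunk = []
        if chunk:
            count += _flush(chunk)
        return CorrelationResult(
            rho=rho, p_two_sided=count / total, n=n, method="exact"
        )

    raise ValueError(f"unknown method {method!r}")


def _ranksum_exact_pmf(n1: int, n2: int) -> np.ndarray:
    """PMF of the rank-sum W of the first sample under the null (no ties).

    Counts subsets of {1..N} of size n1 by sum via dynamic programming;
    index w of the returned array is the rank sum itself.
    """
    N = n1 + n2
    max_sum = sum(range(N - n1 + 1, N + 1))
    dp = np.zeros((n1 + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    return dp[n1] / math.comb(N, n1)


def wilcoxon_rank_sum(x, y) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test on two independent samples.

    Exact null distribution when n1 + n2 <= 20 and there are no ties across
    the pooled sample; otherwise a normal approximation with tie-corrected
    variance and a 0.5 continuity correction. The statistic is the rank sum
    of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    N = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = average_ranks(pooled)
    w = float(ranks[:n1].sum())

    has_ties = np.unique(pooled).size < N
    if N <= 20 and not has_ties:
        pmf = _ranksum_exact_pmf(n1, n2)
        wi = int(round(w))
        p_low = float(pmf[: wi + 1].sum())
        p_high = float(pmf[wi:].sum())
        p = min(1.0, 2.0 * min(p_low, p_high))
        return RankTestResult(statistic=w, p_two_sided=p, n1=n1, n2=n2, method="exact")

    mean_w = n1 * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_w = n1 * n2 * (N + 1) / 12.0 - n1 * n2 * tie_term / (12.0 * N * (N - 1))
    if var_w <= 0:
        return RankTestResult(statistic=w, p_two_sided=1.0, n1=n1, n2=n2, method="normal_approx")
    diff = w - mean_w
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var_w) if diff != 0 else 0.0
    p = min(1.0, 2.0 * float(_norm.sf(abs(z))))
    return RankTestResult(statistic=w, p_two_sided=p, n1=n1, n2=n2, method="normal_approx")
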