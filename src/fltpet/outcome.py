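"""Exploratory outcome analysis: Kaplan-Meier estimation with median survival
and univariate Cox proportional-hazards regression on continuous imaging
parameters.

Both estimators are implemented here (product-limit with Greenwood variance
and log-log confidence bands; Cox partial likelihood maximized by
Newton-Raphson with Efron or Breslow tie handling). Time units are arbitrary
but conventionally months from radiotherapy initiation; patients without the
event are right-censored at last follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm as _norm

Z975 = 1.959963984540054

__all__ = ["SurvivalRecord", "KMResult", "CoxResult", "km_estimate", "cox_univariate"]


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time_months: float
    event: bool
    covariate: float = 0.0

    def __post_init__(self):
        if self.time_months <= 0:
            raise ValueError("survival time must be positive")


@dataclass
class KMResult:
    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float | None  # None = not reached
    median_ci: tuple  # (lower or None, upper or None)
    n: int
    n_events: int


@dataclass
class CoxResult:
    log_hr: float
    se: float
    hr: float
    ci95: tuple
    p: float
    n: int
    n_events: int
    loglik: float
    ties_method: str
    converged: bool


def km_estimate(times, events, conf_level: float = 0.95) -> KMResult:
    """Product-limit survival estimate with log-log (Greenwood) intervals.

    The median is the earliest time with S(t) <= 0.5; its CI bounds are the
    earliest times at which the upper / lower confidence band drops to 0.5.
    With no events the curve is flat at 1 and the median is not reached.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("times and events must be equal-length nonempty 1-D arrays")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    n = t.size
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]

    event_times = np.unique(t[e])
    surv, lo, hi = [], [], []
    s = 1.0
    greenwood = 0.0
    zcrit = float(_norm.ppf(0.5 + conf_level / 2.0))
    for et in event_times:
        at_risk = int(np.count_nonzero(t >= et))
        d = int(np.count_nonzero((t == et) & e))
        s *= 1.0 - d / at_risk
        if at_risk > d:
            greenwood += d / (at_risk * (at_risk - d))
        if 0.0 < s < 1.0 and greenwood > 0.0:
            se_theta = math.sqrt(greenwood) / abs(math.log(s))
            theta = math.log(-math.log(s))
            lo.append(s ** math.exp(zcrit * se_theta))
            hi.append(s ** math.exp(-zcrit * se_theta))
        else:
            lo.append(s)
            hi.append(s)
        surv.append(s)
    surv = np.array(surv)
    lo_a, hi_a = np.array(lo), np.array(hi)

    def _first_below(curve):
        idx = np.nonzero(curve <= 0.5)[0]
        return float(event_times[idx[0]]) if idx.size else None

    median = _first_below(surv) if surv.size else None
    # confidence set for the median: times where the band contains 0.5
    median_ci = (_first_below(lo_a) if surv.size else None,
                 _first_below(hi_a) if surv.size else None)
    return KMResult(
        times=event_times,
        survival=surv,
        ci_lower=lo_a,
        ci_upper=hi_a,
        median=median,
        median_ci=median_ci,
        n=n,
        n_events=int(e.sum()),
    )


def _cox_loglik_score_info(beta, t, e, x, ties):
    """Partial log-likelihood, score and information for one covariate.

    Observations sorted by ascending time; Efron or Breslow handling of tied
    event times.
    """
    eta = beta * x
    exb = np.exp(eta)
    ll = 0.0
    score = 0.0
    info = 0.0
    # suffix sums over the risk set (times >= current)
    n = t.size
    s0_suffix = np.cumsum(exb[::-1])[::-1]
    s1_suffix = np.cumsum((x * exb)[::-1])[::-1]
    s2_suffix = np.cumsum((x * x * exb)[::-1])[::-1]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        death_idx = [k for k in range(i, j + 1) if e[k]]
        d = len(death_idx)
        if d > 0:
            s0, s1, s2 = s0_suffix[i], s1_suffix[i], s2_suffix[i]
            xd = x[death_idx]
            exd = exb[death_idx]
            ll += float(beta * xd.sum())
            if ties == "breslow" or d == 1:
                ll -= d * math.log(s0)
                score += float(xd.sum()) - d * (s1 / s0)
                info += d * (s2 / s0 - (s1 / s0) ** 2)
            elif ties == "efron":
                d0, d1, d2 = float(exd.sum()), float((xd * exd).sum()), float((xd * xd * exd).sum())
                for l in range(d):
                    f = l / d
                    a0 = s0 - f * d0
                    a1 = s1 - f * d1
                    a2 = s2 - f * d2
                    ll -= math.log(a0)
                    score -= a1 / a0
                    info += a2 / a0 - (a1 / a0) ** 2
                score += float(xd.sum())
            else:
                raise ValueError("ties must be 'efron' or 'breslow'")
        i = j + 1
    return ll, score, info


def cox_univariate(times, events, covariate, ties: str = "efron") -> CoxResult:
    """Univariate Cox regression: Newton-Raphson on the partial likelihood.

    The hazard ratio is per one-unit increase of the covariate; the Wald SE
    comes from the observed information at the optimum. Requires at least two
    events; monotone likelihood (perfect separation) is flagged by
    converged=False.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    if not (t.shape == e.shape == x.shape):
        raise ValueError("times, events and covariate must have equal length")
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("no events observed; Cox model cannot be fitted")
    if n_events < 2:
        raise ValueError("need at least 2 events for a stable fit")
    if np.unique(x[e]).size < 2 and np.unique(x).size < 2:
        raise ValueError("covariate is constant")

    order = np.argsort(t, kind="mergesort")
    t, e, x = t[order], e[order], x[order]

    beta = 0.0
    converged = False
    ll, score, info = _cox_loglik_score_info(beta, t, e, x, ties)
    for _ in range(100):
        if info <= 0:
            break
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_loglik_score_info(new_beta, t, e, x, ties)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_loglik_score_info(new_beta, t, e, x, ties)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(score) < 1e-9 and abs(step) < 1e-9:
            converged = True
            break
        if abs(beta) > 50:  # monotone likelihood / separation
            break
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    hr = math.exp(beta)
    ci = (math.exp(beta - Z975 * se), math.exp(beta + Z975 * se))
    p = 2.0 * float(_norm.sf(abs(beta / se))) if se > 0 and math.isfinite(se) else float("nan")
    return CoxResult(
        log_hr=beta,
        se=se,
        hr=hr,
        ci95=ci,
        p=p,
        n=t.size,
        n_events=n_events,
        loglik=ll,
        ties_method=ties,
        converged=converged,
    )
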