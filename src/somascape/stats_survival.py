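"""Survival and enrichment statistics shared by every pipeline stage.

Kaplan-Meier curves and the log-rank test are computed through lifelines;
the univariate Cox model is fit directly by Newton-Raphson on the partial
likelihood with Breslow tie handling so that monotone-likelihood
(perfect-separation) fits are *reported* as non-converged rather than
raised. Hypergeometric tails and Student's t come from scipy, and
Benjamini-Hochberg q values from statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KMFit",
    "CoxResult",
    "km_fit",
    "km_median",
    "logrank_test",
    "cox_univariate",
    "hypergeom_tail",
    "students_t",
    "bh_fdr",
]


@dataclass
class KMFit:
    """Product-limit estimate: S(t) evaluated at the distinct observed times."""

    times: np.ndarray           # distinct event/censor times, ascending
    survival: np.ndarray        # S(t) at those times
    at_risk: np.ndarray         # number at risk just before each time
    n_events: np.ndarray        # deaths at each time
    n: int = 0

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    hr: float
    beta: float
    se: float
    p: float
    converged: bool
    n_events: int = 0
    loglik: float = field(default=float("nan"))


def _as_arrays(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if t.size == 0:
        raise ValueError("empty survival sample")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    return t, e


def km_fit(times, events) -> KMFit:
    """Kaplan-Meier product-limit estimator."""
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tab = kmf.event_table
    # drop the t=0 bookkeeping row unless events/censoring actually occur there
    keep = (tab["removed"] > 0).to_numpy()
    grid = tab.index.to_numpy(dtype=float)[keep]
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    return KMFit(
        times=grid,
        survival=surv,
        at_risk=tab["at_risk"].to_numpy()[keep],
        n_events=tab["observed"].to_numpy()[keep],
        n=int(t.size),
    )


def km_median(fit: KMFit) -> float | None:
    """Smallest t with S(t) <= 0.5, or None when S never reaches 0.5."""
    below = np.nonzero(fit.survival <= 0.5)[0]
    if below.size == 0:
        return None
    return float(fit.times[below[0]])


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p) on 1 df."""
    ta, ea = _as_arrays(times_a, events_a)
    tb, eb = _as_arrays(times_b, events_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(times, events, covariate, max_iter: int = 60,
                   tol: float = 1e-9) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Breslow ties).

    Newton-Raphson on the log partial likelihood. A monotone likelihood
    (the estimate diverging, as when all events fall in one covariate arm)
    is reported via ``converged=False`` with the last stable estimate.
    """
    t, e = _as_arrays(times, events)
    x = np.asarray(covariate, dtype=float)
    if x.shape != t.shape:
        raise ValueError("covariate length mismatch")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    if e.sum() == 0:
        raise ValueError("no events")

    order = np.argsort(-t, kind="stable")  # descending time
    t, e, x = t[order], e[order], x[order]
    # group indices of tied event times (Breslow): risk set = all with time >= t_j
    beta = 0.0
    converged = False
    diverged = False
    loglik = np.nan
    se = np.nan
    for _ in range(max_iter):
        w = np.exp(beta * x)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * x)
        s2 = np.cumsum(w * x * x)
        # for each subject i (descending t), risk-set sums are cumsums up to
        # the last index sharing time >= t_i; with ties we need sums over all
        # subjects with time >= t_i, i.e. cumsum up to end of the tie block.
        uniq, inv = np.unique(-t, return_inverse=True)  # ascending in -t == descending t
        block_end = np.zeros(uniq.size, dtype=int)
        np.maximum.at(block_end, inv, np.arange(t.size))
        idx = block_end[inv]
        S0, S1, S2 = s0[idx], s1[idx], s2[idx]
        ll = float(np.sum(e * (beta * x - np.log(S0))))
        grad = float(np.sum(e * (x - S1 / S0)))
        info = float(np.sum(e * (S2 / S0 - (S1 / S0) ** 2)))
        if info <= 0 or not np.isfinite(info):
            diverged = True
            break
        step = grad / info
        beta_new = beta + step
        if abs(beta_new) > 20:
            diverged = True
            beta = beta_new
            break
        beta = beta_new
        loglik = ll
        se = 1.0 / np.sqrt(info)
        if abs(step) < tol:
            converged = True
            break
    if diverged:
        converged = False
    z = beta / se if se and np.isfinite(se) and se > 0 else np.nan
    p = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return CoxResult(hr=float(np.exp(beta)), beta=float(beta), se=float(se),
                     p=p, converged=converged, n_events=int(e.sum()),
                     loglik=loglik)


def hypergeom_tail(x: int, K: int, N: int, n: int, side: str = "ge") -> float:
    """Exact hypergeometric tail P(X >= x) or P(X <= x).

    X counts marked draws when ``n`` items are drawn without replacement
    from ``N`` of which ``K`` are marked.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if not (0 <= x <= min(K, n)):
        raise ValueError("require 0 <= x <= min(K, n)")
    dist = sps.hypergeom(N, K, n)
    if side == "ge":
        return float(dist.sf(x - 1))
    if side == "le":
        return float(dist.cdf(x))
    raise ValueError("side must be 'ge' or 'le'")


def students_t(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t, two-sided.

    Degenerate zero-variance comparisons with equal means return (0, 1)
    by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float("inf") if np.mean(a) > np.mean(b) else float("-inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
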