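"""Kaplan-Meier estimation, log-rank comparison, two-group Cox fit, and a
log-rank power simulation.

Times are in months from surgery; events are ``dead`` / ``censored``.
Kaplan-Meier curves and the k-sample log-rank test are computed through
lifelines.  The two-group Cox model is a direct Breslow partial-likelihood
Newton fit for a single binary covariate — small enough to own, and it
exposes the score test at beta = 0 (which equals the two-group log-rank
chi-square on tie-free data) plus explicit monotone-likelihood detection.
The power simulator draws exponential survival under a given hazard ratio
and uses an internal vectorised two-group log-rank statistic (tested for
equality against lifelines) so that thousands of replicates stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "KmCurve",
    "LogRankResult",
    "CoxFit",
    "PowerEstimate",
    "km_fit",
    "logrank_test",
    "cox_fit_binary",
    "power_logrank_sim",
    "two_group_logrank_chisq",
]


def _as_event_bool(events) -> np.ndarray:
    events = np.asarray(events)
    if events.dtype.kind in "biu":
        return events.astype(bool)
    if events.dtype.kind == "f":
        if not np.all(np.isin(events, (0.0, 1.0))):
            raise ValueError("numeric event indicators must be 0/1")
        return events.astype(bool)
    out = np.empty(events.shape, dtype=bool)
    for i, e in np.ndenumerate(events):
        token = str(e).lower()
        if token in ("dead", "event", "true", "1"):
            out[i] = True
        elif token in ("censored", "alive", "false", "0"):
            out[i] = False
        else:
            raise ValueError(f"unknown event token {e!r}")
    return out


@dataclass
class KmCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct event times (ascending); subjects censored
    at an event time remain at risk for that time's deaths.  ``median`` is
    None when the curve never crosses 0.5.
    """

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    n: int
    median: Optional[float]

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    groups: tuple
    chi_square: float
    df: int
    p_value: float


@dataclass(frozen=True)
class CoxFit:
    log_hazard_ratio: float
    se: float
    hazard_ratio: float
    converged: bool
    iterations: int
    score_chi2: float  # score test at beta = 0

    @property
    def p_value(self) -> float:
        """Wald p-value for log HR = 0."""
        if not np.isfinite(self.se) or self.se == 0:
            return float("nan")
        z = self.log_hazard_ratio / self.se
        return float(2 * sps.norm.sf(abs(z)))


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    ci_low: float
    ci_high: float
    reps: int
    rejections: int
    alpha: float
    hazard_ratio: float
    n_total: int


def km_fit(times, events) -> KmCurve:
    times = np.asarray(times, dtype=float)
    observed = _as_event_bool(events)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=observed)
    table = kmf.event_table
    mask = table["observed"] > 0
    event_times = table.index[mask].to_numpy(dtype=float)
    at_risk = table.loc[mask, "at_risk"].to_numpy(dtype=int)
    d = table.loc[mask, "observed"].to_numpy(dtype=int)
    surv = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    median = float(kmf.median_survival_time_)
    return KmCurve(
        times=event_times,
        at_risk=at_risk,
        events=d,
        survival=surv,
        n=int(times.size),
        median=None if np.isinf(median) else median,
    )


def logrank_test(times, events, grouping) -> LogRankResult:
    """k-sample log-rank test (observed minus expected over shared event
    times), supporting two or more groups."""
    times = np.asarray(times, dtype=float)
    observed = _as_event_bool(events)
    groups = np.asarray(grouping)
    labels = tuple(sorted(pd.unique(groups).tolist()))
    if len(labels) < 2:
        raise ValueError("at least two groups required")
    if observed.sum() == 0:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(times, groups, observed)
    return LogRankResult(
        groups=labels,
        chi_square=float(res.test_statistic),
        df=len(labels) - 1,
        p_value=float(res.p_value),
    )


# ---------------------------------------------------------------------------
# binary-covariate Cox model (Breslow ties)


def _breslow_quantities(beta: float, times: np.ndarray, observed: np.ndarray,
                        z: np.ndarray) -> tuple[float, float, float]:
    """(log partial likelihood, score U, information I) at beta.

    Risk sets are computed per distinct event time; with a binary covariate
    the risk-set sums reduce to counts n0, n1 of at-risk subjects per group.
    """
    loglik = 0.0
    score = 0.0
    info = 0.0
    eb = np.exp(beta)
    for t in np.unique(times[observed]):
        at_risk = times >= t
        n1 = int(np.sum(at_risk & (z == 1)))
        n0 = int(np.sum(at_risk)) - n1
        dying = observed & (times == t)
        d = int(dying.sum())
        d1 = int(np.sum(dying & (z == 1)))
        s0 = n0 + n1 * eb
        mu = n1 * eb / s0
        loglik += beta * d1 - d * np.log(s0)
        score += d1 - d * mu
        info += d * mu * (1 - mu)
    return loglik, score, info


def cox_fit_binary(times, events, group) -> CoxFit:
    """Cox proportional-hazards fit for one binary covariate.

    Maximises the Breslow partial likelihood by Newton iteration with step
    halving.  When the partial likelihood is monotone (one group's events
    all precede the other's risk sets emptying), the estimate diverges; this
    is reported as ``converged=False`` with the last iterate.
    """
    times = np.asarray(times, dtype=float)
    observed = _as_event_bool(events)
    z = np.asarray(group)
    uniq = np.unique(z)
    if uniq.size != 2:
        raise ValueError(f"group must be binary, got levels {uniq.tolist()}")
    z = (z == uniq[1]).astype(int)
    if observed.sum() == 0:
        raise ValueError("no events observed")

    _, u0, i0 = _breslow_quantities(0.0, times, observed, z)
    score_chi2 = float(u0**2 / i0) if i0 > 0 else 0.0

    beta = 0.0
    loglik, score, info = _breslow_quantities(beta, times, observed, z)
    converged = False
    it = 0
    for it in range(1, 51):
        if info <= 0:
            break
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = _breslow_quantities(new_beta, times, observed, z)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 30:
            step /= 2
            new_beta = beta + step
            new_ll, new_score, new_info = _breslow_quantities(
                new_beta, times, observed, z
            )
            halvings += 1
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if abs(score) < 1e-9 or abs(step) < 1e-12:
            converged = True
            break
    if abs(beta) > 15:
        converged = False  # monotone partial likelihood / separation
    se = float(1 / np.sqrt(info)) if info > 0 else float("inf")
    return CoxFit(
        log_hazard_ratio=float(beta),
        se=se,
        hazard_ratio=float(np.exp(beta)),
        converged=converged,
        iterations=it,
        score_chi2=score_chi2,
    )


# ---------------------------------------------------------------------------
# power simulation


def two_group_logrank_chisq(times: np.ndarray, observed: np.ndarray,
                            group: np.ndarray) -> float:
    """Two-group log-rank chi-square with the hypergeometric variance.

    Internal fast path for simulation loops; equals
    :func:`logrank_test` (lifelines) on the same data.
    """
    o1 = 0.0
    e1 = 0.0
    v = 0.0
    for t in np.unique(times[observed]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int(np.sum(at_risk & group))
        dying = observed & (times == t)
        d = int(dying.sum())
        d1 = int(np.sum(dying & group))
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v <= 0:
        return 0.0
    return float((o1 - e1) ** 2 / v)


CensoringRule = Callable[[np.random.Generator, int], np.ndarray]


def power_logrank_sim(hazard_ratio: float, n_total: int, allocation: float = 0.5,
                      alpha: float = 0.05, censoring_rule: Optional[CensoringRule] = None,
                      reps: int = 5000, seed: int = 1) -> PowerEstimate:
    """Empirical power of the two-sided two-group log-rank test.

    Each replicate draws exponential survival times: the reference group at
    unit rate, the comparison group at rate ``hazard_ratio`` (the log-rank
    test is invariant to the common time scale).  ``censoring_rule``, if
    given, maps ``(rng, n)`` to per-subject censoring times; the default is
    no censoring (every event observed).  Power is the fraction of
    replicates rejecting at level ``alpha``, with a Wilson binomial CI.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if reps < 100:
        raise ValueError("reps must be at least 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n1 = int(round(n_total * allocation))
    n0 = n_total - n1
    if n0 < 1 or n1 < 1:
        raise ValueError(f"allocation {allocation} leaves an empty group")
    crit = sps.chi2.ppf(1 - alpha, df=1)
    rng = np.random.default_rng(seed)
    group = np.concatenate([np.zeros(n0, dtype=bool), np.ones(n1, dtype=bool)])
    rejections = 0
    for _ in range(reps):
        t0 = rng.exponential(1.0, size=n0)
        t1 = rng.exponential(1.0 / hazard_ratio, size=n1)
        times = np.concatenate([t0, t1])
        observed = np.ones(n_total, dtype=bool)
        if censoring_rule is not None:
            c = np.asarray(censoring_rule(rng, n_total), dtype=float)
            observed = times <= c
            times = np.minimum(times, c)
        if observed.sum() == 0:
            continue
        if two_group_logrank_chisq(times, observed, group) > crit:
            rejections += 1
    power = rejections / reps
    ci_low, ci_high = proportion_confint(rejections, reps, alpha=0.05, method="wilson")
    return PowerEstimate(
        power=power,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        reps=reps,
        rejections=rejections,
        alpha=alpha,
        hazard_ratio=hazard_ratio,
        n_total=n_total,
    )
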