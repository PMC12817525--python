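"""Kaplan–Meier estimation, log-rank tests, and binary-covariate Cox regression.

The KM estimator and the log-rank test are delegated to ``lifelines``; the
single :func:`logrank_statistic` implementation here is shared by every
module that compares survival between two groups, so a cutpoint search and a
downstream report can never disagree.

The Cox model is restricted to one binary covariate (the only form the
stratified analyses need) and fitted by a one-dimensional Newton iteration
on the Breslow partial likelihood.  For a binary covariate the Breslow
log-partial-likelihood reduces to

    l(b) = b * d1 - sum_j d_j * log(n0_j + n1_j * exp(b)),

summing over distinct event times j with d_j events and n0_j / n1_j
at-risk subjects per group, d1 the total events in group 1.  The score test
at b = 0 is the classical log-rank statistic (exactly so in the absence of
ties), which is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats

__all__ = [
    "KMCurve",
    "LogrankResult",
    "CoxResult",
    "GroupSurvivalSummary",
    "km_estimate",
    "logrank_statistic",
    "cox_binary",
    "mean_survival",
]

#: |log HR| cap applied when the partial likelihood is monotone
_COEF_CAP = 15.0


def _as_arrays(durations, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("durations and events must be 1-D and equal length")
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t < 0):
        raise ValueError("survival times must be >= 0")
    return t, e


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve evaluated at the observed times."""

    times: np.ndarray              # distinct observed times, ascending
    survival: np.ndarray           # S(t) at those times
    at_risk: np.ndarray            # risk-set size just before each time
    censor_times: np.ndarray       # times of censored observations

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogrankResult:
    statistic: float   # one-degree-of-freedom chi-square
    p_value: float


@dataclass(frozen=True)
class CoxResult:
    coef: float                    # log hazard ratio (group 1 vs group 0)
    hazard_ratio: float
    se: float
    ci_lower: float
    ci_upper: float
    wald_p: float
    logrank_p: float
    n_events: tuple[int, int]      # events in group 0, group 1
    estimable: bool                # False when a group has no events
    unstable: bool                 # True when either group has < 5 events


@dataclass(frozen=True)
class GroupSurvivalSummary:
    mean_by_group: dict
    difference: float              # mean(group 1) - mean(group 0)
    method: Literal["arithmetic", "rmst"]
    horizon: Optional[float] = None


def km_estimate(durations: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan–Meier product-limit estimate.

    Censored subjects leave the risk set without contributing a step.
    """
    t, e = _as_arrays(durations, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    # lifelines includes t=0; keep observed times only, S(0)=1 implied
    mask = np.isin(times, np.unique(t))
    ev = kmf.event_table
    at_risk = ev.loc[times[mask], "at_risk"].to_numpy(dtype=float)
    return KMCurve(
        times=times[mask],
        survival=surv[mask],
        at_risk=at_risk,
        censor_times=np.sort(t[~e]),
    )


def logrank_statistic(
    durations_a: Sequence[float],
    events_a: Sequence[bool],
    durations_b: Sequence[float],
    events_b: Sequence[bool],
) -> LogrankResult:
    """Two-group log-rank test (1-df chi-square, hypergeometric variance)."""
    ta, ea = _as_arrays(durations_a, events_a)
    tb, eb = _as_arrays(durations_b, events_b)
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def _breslow_terms(t, e, g):
    """Distinct event times with per-group risk counts and event counts."""
    event_times = np.unique(t[e])
    out = []
    for tau in event_times:
        at_risk = t >= tau
        n0 = int(np.sum(at_risk & (g == 0)))
        n1 = int(np.sum(at_risk & (g == 1)))
        d = int(np.sum(e & (t == tau)))
        d1 = int(np.sum(e & (t == tau) & (g == 1)))
        out.append((n0, n1, d, d1))
    return out


def cox_binary(
    durations: Sequence[float],
    events: Sequence[bool],
    group: Sequence[int],
    alpha: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Cox proportional hazards for a single binary covariate (Breslow ties).

    Newton iteration to gradient tolerance ``tol``.  When one group has no
    events the partial likelihood is monotone: the coefficient is capped at
    +/-15 and the fit flagged non-estimable.  Wald intervals are flagged
    ``unstable`` when either group has fewer than 5 events.
    """
    t, e = _as_arrays(durations, events)
    g = np.asarray(group, dtype=int)
    if g.shape != t.shape:
        raise ValueError("group indicator must align with durations")
    if not set(np.unique(g)) <= {0, 1}:
        raise ValueError("group must be coded 0/1")
    d0 = int(np.sum(e & (g == 0)))
    d1 = int(np.sum(e & (g == 1)))
    estimable = d0 > 0 and d1 > 0

    terms = _breslow_terms(t, e, g)
    s1 = sum(term[3] for term in terms)

    def grad_hess(beta: float) -> tuple[float, float]:
        eb = np.exp(beta)
        grad = float(s1)
        hess = 0.0
        for n0, n1, d, _ in terms:
            denom = n0 + n1 * eb
            mu = n1 * eb / denom
            grad -= d * mu
            hess -= d * mu * (1 - mu)
        return grad, hess

    beta = 0.0
    for _ in range(max_iter):
        grad, hess = grad_hess(beta)
        if abs(grad) < tol:
            break
        if hess == 0.0:
            break
        beta -= grad / hess
        if abs(beta) > _COEF_CAP:
            beta = float(np.clip(beta, -_COEF_CAP, _COEF_CAP))
            break

    _, hess = grad_hess(beta)
    info = -hess
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    z = stats.norm.ppf(1 - alpha / 2)
    hr = float(np.exp(beta))
    if np.isfinite(se) and se > 0:
        wald_p = float(2 * stats.norm.sf(abs(beta) / se))
        with np.errstate(over="ignore"):
            ci_lower, ci_upper = float(np.exp(beta - z * se)), float(np.exp(beta + z * se))
    else:
        wald_p, ci_lower, ci_upper = float("nan"), 0.0, float("inf")

    lr = logrank_statistic(t[g == 0], e[g == 0], t[g == 1], e[g == 1])
    return CoxResult(
        coef=float(beta),
        hazard_ratio=hr,
        se=se,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        wald_p=wald_p,
        logrank_p=lr.p_value,
        n_events=(d0, d1),
        estimable=estimable,
        unstable=(d0 < 5 or d1 < 5),
    )


def mean_survival(
    durations: Sequence[float],
    events: Sequence[bool],
    group: Sequence[int],
    method: Literal["arithmetic", "rmst"] = "arithmetic",
    horizon: float = 60.0,
) -> GroupSurvivalSummary:
    """Per-group mean survival and their difference.

    ``arithmetic`` pools events and censorings and averages the recorded
    follow-up times; ``rmst`` integrates the group KM curve up to
    ``horizon`` (restricted mean survival time).  Both are reported because
    published "mean survival" figures rarely state their estimator.
    """
    t, e = _as_arrays(durations, events)
    g = np.asarray(group, dtype=int)
    if g.shape != t.shape:
        raise ValueError("group indicator must align with durations")
    means: dict = {}
    for level in sorted(np.unique(g)):
        sel = g == level
        if method == "arithmetic":
            means[int(level)] = float(np.mean(t[sel]))
        elif method == "rmst":
            kmf = KaplanMeierFitter().fit(t[sel], event_observed=e[sel])
            means[int(level)] = float(restricted_mean_survival_time(kmf, t=horizon))
        else:
            raise ValueError(f"unknown method {method!r}")
    levels = sorted(means)
    diff = means[levels[-1]] - means[levels[0]] if len(levels) > 1 else 0.0
    return GroupSurvivalSummary(
        mean_by_group=means,
        difference=float(diff),
        method=method,
        horizon=horizon if method == "rmst" else None,
    )
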