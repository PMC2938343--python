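"""Kaplan-Meier estimation and the two-group log-rank test.

These score the survival half of the pipeline: samples predicted into the
dead-labelled groups form the high-risk arm, the alive-labelled ones the
low-risk arm, and their observed follow-up is compared.

Conventions: right censoring; a subject censored at an event time is still
at risk for that event; the log-rank statistic uses the hypergeometric
variance at each distinct event time and is referred to chi-square with one
degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate evaluated at the distinct event times."""

    event_times: np.ndarray  # ascending distinct times with >= 1 event
    at_risk: np.ndarray      # n_t at each event time
    events: np.ndarray       # d_t at each event time
    survival: np.ndarray     # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event time."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float     # chi-square value, 1 df
    p_value: float       # upper-tail probability
    group_sizes: tuple[int, int]


def _check_surv(times: Sequence[float], events: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if (t <= 0).any():
        raise ValueError("all follow-up times must be > 0")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    return t, e.astype(int)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMEstimate:
    """Kaplan-Meier product-limit estimator S(t) = prod_{tau <= t} (1 - d/n)."""
    t, e = _check_surv(times, events)
    event_times = np.unique(t[e == 1])
    at_risk = np.array([(t >= tau).sum() for tau in event_times], dtype=int)
    d = np.array([((t == tau) & (e == 1)).sum() for tau in event_times], dtype=int)
    with np.errstate(invalid="ignore"):
        survival = np.cumprod(1.0 - d / np.maximum(at_risk, 1))
    return KMEstimate(event_times=event_times, at_risk=at_risk, events=d,
                      survival=survival)


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> LogRankResult:
    """Standard (unweighted) two-group log-rank test.

    At each distinct pooled event time, the observed events in group A are
    compared with the expectation d * n_a / n under the null, with
    hypergeometric variance d (n_a/n) (n_b/n) (n - d)/(n - 1).  The statistic
    (sum O - E)^2 / sum Var is referred to chi-square(1).  If the pooled data
    contain no events (or the variance degenerates), the result is
    statistic 0, p = 1.
    """
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    pooled_event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for tau in pooled_event_times:
        na = (ta >= tau).sum()
        nb = (tb >= tau).sum()
        n = na + nb
        da = ((ta == tau) & (ea == 1)).sum()
        db = ((tb == tau) & (eb == 1)).sum()
        d = da + db
        if n < 2 or d == 0:
            continue
        o_minus_e += da - d * na / n
        var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if var <= 0.0:
        return LogRankResult(0.0, 1.0, (ta.size, tb.size))
    statistic = o_minus_e ** 2 / var
    p = float(stats.chi2.sf(statistic, df=1))
    return LogRankResult(float(statistic), max(p, np.finfo(float).tiny),
                         (ta.size, tb.size))
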