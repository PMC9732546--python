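"""RTV-fold progression events, Kaplan–Meier estimation, log-rank comparison.

Progression endpoints are defined on the RTV scale: a mouse has an event at
the first measurement day on which its relative tumor volume reaches a fold
threshold (x2 = tumor doubling, x4 = quadrupling). Mice that never cross the
threshold (sacrificed at the volume ceiling or alive at study end) are
censored at their last measurement day. Estimation and the Mantel–Cox
log-rank test are performed with lifelines; events precede censorings at
tied times, and the log-rank variance is the per-time hypergeometric form
without continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ValidationError
from .growth import GrowthCurve, StudyArm, rtv_series

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogrankResult",
    "event_time",
    "arm_event_times",
    "km_estimate",
    "logrank_test",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Time-to-progression (or censoring) of one mouse at one fold threshold."""

    mouse_id: str
    fold_threshold: int
    time: int
    event: bool
    arm_label: str = ""

    def __post_init__(self) -> None:
        if self.fold_threshold not in (2, 4):
            raise ValidationError(
                f"fold threshold must be 2 or 4, got {self.fold_threshold}"
            )
        if not self.time > 0:
            raise ValidationError(f"time must be positive, got {self.time}")


@dataclass(frozen=True)
class KMCurve:
    """Kaplan–Meier product-limit estimate.

    ``times`` holds every distinct observed time (events and censorings),
    ``survival`` the estimate just after each time. The curve starts at 1
    (implicitly, at t=0) and is non-increasing.
    """

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    n_events: tuple[int, ...]
    censor_times: tuple[float, ...]

    def survival_at(self, t: float) -> float:
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p: float


def event_time(curve: GrowthCurve, fold: int) -> SurvivalRecord:
    """First measurement day with RTV >= ``fold``, or censoring at last day.

    No interpolation between the (weekly) measurement days is attempted: the
    event time is the first observed crossing. A curve that never crosses —
    including a single-measurement curve — is censored at its last
    measurement day.
    """
    if fold not in (2, 4):
        raise ValidationError(f"fold threshold must be 2 or 4, got {fold}")
    series = rtv_series(curve)
    for day, rtv in series:
        if rtv >= fold:
            return SurvivalRecord(curve.mouse_id, fold, day, True, curve.arm_label)
    last_day = series[-1][0]
    return SurvivalRecord(curve.mouse_id, fold, last_day, False, curve.arm_label)


def arm_event_times(arm: StudyArm, fold: int) -> list[SurvivalRecord]:
    """Event/censor records for every mouse of an arm."""
    return [event_time(c, fold) for c in arm.curves]


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate from event/censor records."""
    if not records:
        raise ValidationError("cannot estimate a survival curve from no records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    tab = tab[tab.index > 0]  # drop the synthetic t=0 row
    obs_times = tab.index.to_numpy(dtype=float)
    survival = kmf.survival_function_at_times(obs_times).to_numpy(dtype=float)
    censor_times = tuple(float(t) for t, row in tab.iterrows() if row["censored"] > 0)
    return KMCurve(
        times=tuple(float(t) for t in obs_times),
        survival=tuple(float(s) for s in survival),
        at_risk=tuple(int(v) for v in tab["at_risk"]),
        n_events=tuple(int(v) for v in tab["observed"]),
        censor_times=censor_times,
    )


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogrankResult:
    """Two-group Mantel–Cox log-rank test (1 df, two-sided chi-square p).

    With no event in either group there is nothing to compare: the test
    returns chi-square 0 and p = 1 with a warning.
    """
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    ta = np.array([r.time for r in group_a], dtype=float)
    ea = np.array([r.event for r in group_a], dtype=bool)
    tb = np.array([r.time for r in group_b], dtype=float)
    eb = np.array([r.event for r in group_b], dtype=bool)
    if not (ea.any() or eb.any()):
        warnings.warn(
            "no events in either group; log-rank p-value set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return LogrankResult(0.0, 1.0)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(float(res.test_statistic), float(res.p_value))
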