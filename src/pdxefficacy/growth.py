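"""Tumor growth metrics for PDX efficacy studies.

Converts caliper measurements into volumes, relative tumor volumes (RTV),
arm-level tumor growth inhibition (TGI), and per-mouse response
classification (RTVV / ORR).

Conventions
-----------
* Day 1 is treatment initiation; every growth curve starts at day 1 and its
  RTV at day 1 is exactly 1.
* RTV = V_x / V_1 — a mouse's volume normalized to its own day-1 baseline.
* TGI(day) = 100 − 100 · median(RTV treated) / median(RTV control), in
  percent; a TGI of at least 50% is flagged as a biologically meaningful
  effect.
* RTVV = (treated mouse RTV) / (median control RTV) at the end of treatment;
  ORR = RTVV − 1; a mouse is a responder iff ORR < −0.5 (strict).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Literal, Optional, Sequence

from .errors import NotEvaluableError, ValidationError

__all__ = [
    "TumorMeasurement",
    "GrowthCurve",
    "StudyArm",
    "Study",
    "TgiResult",
    "ResponseRecord",
    "OrrTableRow",
    "volume_from_diameters",
    "rtv_series",
    "rtv_at",
    "last_rtv",
    "median_rtv",
    "tgi_series",
    "optimal_tgi",
    "classify_response",
    "orr_table",
    "last_common_day",
    "responder_percentage",
]

VolumeConvention = Literal["as-printed", "conventional"]

#: terminal states of a growth curve
ALIVE = "alive-at-study-end"
SACRIFICED = "sacrificed"


def volume_from_diameters(
    a: float, b: float, convention: VolumeConvention = "as-printed"
) -> float:
    """Tumor volume (mm³) from two perpendicular caliper diameters (mm).

    ``a`` is the largest and ``b`` the smallest perpendicular diameter.

    Two conventions are supported:

    * ``"as-printed"`` — V = (a·b)²/2, the formula as stated in the study
      protocol this package reproduces. It is dimensionally anomalous (mm⁴)
      but all RTV-based downstream metrics are ratios and therefore
      invariant to the convention, provided one convention is used
      throughout a study.
    * ``"conventional"`` — V = a·b²/2, the standard ellipsoid
      approximation used across the xenograft literature.
    """
    if not (a > 0 and b > 0):
        raise ValidationError(f"diameters must be positive, got a={a}, b={b}")
    if a < b:
        raise ValidationError(
            f"largest diameter a={a} is smaller than smallest diameter b={b}"
        )
    if convention == "as-printed":
        return (a * b) ** 2 / 2.0
    if convention == "conventional":
        return a * b * b / 2.0
    raise ValidationError(f"unknown volume convention: {convention!r}")


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper measurement of one mouse on one study day."""

    mouse_id: str
    day: int
    volume: float
    diameter_a: Optional[float] = None
    diameter_b: Optional[float] = None

    def __post_init__(self) -> None:
        if int(self.day) != self.day or self.day < 1:
            raise ValidationError(
                f"day must be an integer >= 1 (day 1 = treatment start), got {self.day}"
            )
        if not self.volume > 0:
            raise ValidationError(
                f"volume must be positive, got {self.volume} for mouse "
                f"{self.mouse_id} day {self.day}"
            )
        if (self.diameter_a is None) != (self.diameter_b is None):
            raise ValidationError("either both diameters or neither must be given")
        if self.diameter_a is not None and self.diameter_b is not None:
            if not (self.diameter_a >= self.diameter_b > 0):
                raise ValidationError(
                    f"diameters must satisfy a >= b > 0, got "
                    f"a={self.diameter_a}, b={self.diameter_b}"
                )


@dataclass(frozen=True)
class GrowthCurve:
    """Ordered tumor measurements of a single mouse.

    The first measurement must be on day 1; its volume is the baseline V1
    against which all RTVs of this mouse are computed.
    """

    mouse_id: str
    arm_label: str
    measurements: tuple[TumorMeasurement, ...]
    terminal_status: str = ALIVE

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValidationError(f"curve {self.mouse_id} has no measurements")
        days = [m.day for m in self.measurements]
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise ValidationError(
                f"curve {self.mouse_id}: days must be strictly increasing, got {days}"
            )
        if days[0] != 1:
            raise ValidationError(
                f"curve {self.mouse_id}: first measurement must be day 1, got day {days[0]}"
            )
        for m in self.measurements:
            if m.mouse_id != self.mouse_id:
                raise ValidationError(
                    f"measurement of mouse {m.mouse_id} inside curve {self.mouse_id}"
                )
        if self.terminal_status not in (ALIVE, SACRIFICED):
            raise ValidationError(
                f"terminal_status must be {ALIVE!r} or {SACRIFICED!r}, "
                f"got {self.terminal_status!r}"
            )

    @property
    def baseline_volume(self) -> float:
        """V1, the tumor volume at treatment initiation (day 1)."""
        return self.measurements[0].volume

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(m.day for m in self.measurements)

    @property
    def volumes(self) -> tuple[float, ...]:
        return tuple(m.volume for m in self.measurements)

    def measured_on(self, day: int) -> bool:
        return any(m.day == day for m in self.measurements)


@dataclass(frozen=True)
class StudyArm:
    """A named study arm: one treatment (or control) and its mice."""

    name: str
    curves: tuple[GrowthCurve, ...]
    treatment_label: str = ""

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValidationError(f"arm {self.name!r} has no mice")
        for c in self.curves:
            if c.arm_label != self.name:
                raise ValidationError(
                    f"curve {c.mouse_id} labelled {c.arm_label!r} inside arm {self.name!r}"
                )
        ids = [c.mouse_id for c in self.curves]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate mouse ids in arm {self.name!r}: {ids}")

    @property
    def n_mice(self) -> int:
        return len(self.curves)

    @property
    def measurement_days(self) -> tuple[int, ...]:
        return tuple(sorted({m.day for c in self.curves for m in c.measurements}))


@dataclass(frozen=True)
class Study:
    """A full study: one control arm plus one or more treated arms."""

    arms: tuple[StudyArm, ...]
    control_name: str = "control"

    def __post_init__(self) -> None:
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate arm names: {names}")
        if self.control_name not in names:
            raise ValidationError(
                f"control arm {self.control_name!r} not among arms {names}"
            )

    @property
    def control_arm(self) -> StudyArm:
        return next(a for a in self.arms if a.name == self.control_name)

    @property
    def treated_arms(self) -> tuple[StudyArm, ...]:
        return tuple(a for a in self.arms if a.name != self.control_name)

    def arm(self, name: str) -> StudyArm:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(name)


@dataclass(frozen=True)
class TgiResult:
    """Tumor growth inhibition of one treated arm at one day."""

    day: int
    rtv_treated_median: float
    rtv_control_median: float
    tgi_percent: float
    meaningful: bool


@dataclass(frozen=True)
class ResponseRecord:
    """Per-mouse response classification.

    ``rtvv`` is the mouse's RTV divided by the control arm's median RTV at
    ``evaluation_day``; ``orr`` = rtvv − 1; ``responder`` is True iff
    orr < −0.5 strictly. ``used_last_available`` marks mice that were no
    longer measured on the evaluation day and contributed their last
    recorded RTV instead.
    """

    mouse_id: str
    rtvv: float
    orr: float
    responder: bool
    evaluation_day: int
    used_last_available: bool = False


# ---------------------------------------------------------------------------
# RTV
# ---------------------------------------------------------------------------

def rtv_series(curve: GrowthCurve) -> list[tuple[int, float]]:
    """Relative tumor volume (V_day / V1) for each measured day.

    The entry for day 1 is exactly 1.
    """
    v1 = curve.baseline_volume
    return [(m.day, m.volume / v1) for m in curve.measurements]


def rtv_at(curve: GrowthCurve, day: int) -> float:
    """RTV of one mouse at one day; raises if the mouse was not measured then."""
    for m in curve.measurements:
        if m.day == day:
            return m.volume / curve.baseline_volume
    raise NotEvaluableError(f"mouse {curve.mouse_id} has no measurement at day {day}")


def last_rtv(curve: GrowthCurve) -> tuple[int, float]:
    """The mouse's last recorded (day, RTV)."""
    m = curve.measurements[-1]
    return m.day, m.volume / curve.baseline_volume


# ---------------------------------------------------------------------------
# Arm-level metrics
# ---------------------------------------------------------------------------

def _arm_rtvs_at(arm: StudyArm, day: int) -> list[float]:
    return [
        rtv_at(c, day) for c in arm.curves if c.measured_on(day)
    ]


def median_rtv(arm: StudyArm, day: int) -> float:
    """Median RTV over the arm's mice measured at ``day``.

    With an even number of mice the median is the arithmetic mean of the two
    central values.
    """
    values = _arm_rtvs_at(arm, day)
    if not values:
        raise NotEvaluableError(f"arm {arm.name!r}: no mouse measured at day {day}")
    return float(statistics.median(values))


def tgi_series(
    treated: StudyArm, control: StudyArm, min_evaluable: int = 2
) -> list[TgiResult]:
    """TGI(day) = 100 − 100·RTVt/RTVc over all evaluable common days.

    A day is evaluable when each arm still has at least ``min_evaluable``
    measured mice (medians of near-empty arms are unstable). TGI can be
    negative when the treated arm grows faster than control.
    """
    common = sorted(set(treated.measurement_days) & set(control.measurement_days))
    results: list[TgiResult] = []
    for day in common:
        rt = _arm_rtvs_at(treated, day)
        rc = _arm_rtvs_at(control, day)
        if len(rt) < min_evaluable or len(rc) < min_evaluable:
            continue
        med_t = float(statistics.median(rt))
        med_c = float(statistics.median(rc))
        if med_c <= 0:
            raise NotEvaluableError(f"control median RTV is not positive at day {day}")
        tgi = 100.0 - (med_t / med_c * 100.0)
        results.append(
            TgiResult(
                day=day,
                rtv_treated_median=med_t,
                rtv_control_median=med_c,
                tgi_percent=tgi,
                meaningful=tgi >= 50.0,
            )
        )
    if not results:
        raise NotEvaluableError(
            f"arms {treated.name!r} and {control.name!r} share no evaluable day "
            f"with >= {min_evaluable} measured mice per arm"
        )
    return results


def optimal_tgi(
    treated: StudyArm, control: StudyArm, min_evaluable: int = 2
) -> TgiResult:
    """The TgiResult with maximal TGI over evaluable days (earliest day on ties).

    This is the arm's antitumor activity "at the time point when the effect
    was optimal".
    """
    series = tgi_series(treated, control, min_evaluable=min_evaluable)
    best = series[0]
    for r in series[1:]:
        if r.tgi_percent > best.tgi_percent:
            best = r
    return best


# ---------------------------------------------------------------------------
# Per-mouse response classification
# ---------------------------------------------------------------------------

def last_common_day(arm_a: StudyArm, arm_b: StudyArm) -> int:
    """Last day on which both arms still have at least one measured mouse."""
    common = set(arm_a.measurement_days) & set(arm_b.measurement_days)
    if not common:
        raise NotEvaluableError(
            f"arms {arm_a.name!r} and {arm_b.name!r} share no measurement day"
        )
    return max(common)


def classify_response(
    mouse: GrowthCurve, control: StudyArm, evaluation_day: int
) -> ResponseRecord:
    """Classify one treated mouse as responder / non-responder.

    RTVV = RTV(mouse) / median RTV(control) at ``evaluation_day`` (the end
    of treatment); ORR = RTVV − 1; responder iff ORR < −0.5 strictly, so an
    ORR of exactly −0.5 is a non-responder. A mouse sacrificed before the
    evaluation day contributes its last recorded RTV and is flagged.
    """
    med_c = median_rtv(control, evaluation_day)
    if med_c == 0:
        raise NotEvaluableError("control median RTV is zero; RTVV undefined")
    if mouse.measured_on(evaluation_day):
        rtv_m = rtv_at(mouse, evaluation_day)
        flagged = False
    else:
        _, rtv_m = last_rtv(mouse)
        flagged = True
    rtvv = rtv_m / med_c
    orr = rtvv - 1.0
    return ResponseRecord(
        mouse_id=mouse.mouse_id,
        rtvv=rtvv,
        orr=orr,
        responder=orr < -0.5,
        evaluation_day=evaluation_day,
        used_last_available=flagged,
    )


def responder_percentage(n_responders: int, n_total: int) -> float:
    """Responder fraction as a percentage rounded half-up to 1 decimal.

    3 of 16 gives 18.8, matching the conventional reporting style.
    """
    if n_total <= 0:
        raise ValidationError("cannot compute a percentage of an empty arm")
    pct = Decimal(100 * n_responders) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OrrTableRow:
    """One treated arm's responder counts at its evaluation day."""

    arm: str
    n_responders: int
    n_non_responders: int
    responder_pct: float
    evaluation_day: int
    records: tuple[ResponseRecord, ...] = field(compare=False, default=())

    @property
    def n_mice(self) -> int:
        return self.n_responders + self.n_non_responders


def orr_table(
    arms: Sequence[StudyArm],
    control: StudyArm,
    evaluation_day: Optional[int] = None,
) -> list[OrrTableRow]:
    """Responder / non-responder contingency rows, one per treated arm.

    When ``evaluation_day`` is None each arm is evaluated at its own last
    measurement day shared with the control arm.
    """
    rows: list[OrrTableRow] = []
    for arm in arms:
        day = evaluation_day if evaluation_day is not None else last_common_day(arm, control)
        records = tuple(classify_response(c, control, day) for c in arm.curves)
        n_resp = sum(r.responder for r in records)
        rows.append(
            OrrTableRow(
                arm=arm.name,
                n_responders=n_resp,
                n_non_responders=len(records) - n_resp,
                responder_pct=responder_percentage(n_resp, len(records)),
                evaluation_day=day,
                records=records,
            )
        )
    return rows
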