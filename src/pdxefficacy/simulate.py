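"""Synthetic PDX cohort and qPCR table generator.

Emulates the design of a slow-growing xenograft efficacy study so that the
whole analysis pipeline is testable without animal data:

* per-mouse exponential latent growth V(t) = V1·exp(g_i·(1−e)·(t−1)), with
  the per-mouse rate g_i drawn lognormally around the cohort rate g
  (median-preserving parameterization) and treatment acting from day 1 as a
  multiplicative rate reduction e (0 = no effect, 1 = full growth arrest);
* enrollment volumes uniform on a 60–150 mm³ window, measurements every 7
  days starting on day 1, multiplicative lognormal measurement noise;
* per-mouse sacrifice as soon as an observed volume reaches 500 mm³,
  otherwise follow-up ends at ``max_followup`` with the mouse alive;
* arms of 4–7 mice.

The default cohort growth rate g = 0.025/day lets an untreated tumor grow
roughly five-fold in about nine weeks, so control arms reach the sacrifice
volume inside a 49–85 day study window, matching the cadence the analysis
expects. Randomness flows from a single seed; per-mouse generators are
spawned deterministically from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .errors import ValidationError
from .growth import ALIVE, SACRIFICED, GrowthCurve, Study, StudyArm, TumorMeasurement
from .qpcr import REFERENCE_GENE, CtRecord

__all__ = ["SimConfig", "simulate_curve", "simulate_study", "simulate_ct_table"]


def _lognormal_sigma(cv: float) -> float:
    """Sigma of a lognormal with coefficient of variation ``cv``."""
    return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    ``n_per_arm`` may be a fixed integer or an inclusive (low, high) range
    from which each arm's size is drawn. ``growth_rate`` is the cohort
    median per-day log-growth; ``growth_cv`` the between-mouse lognormal
    coefficient of variation of that rate; ``measurement_noise_cv`` the CV
    of the multiplicative lognormal error on every observed volume
    (median-1, so noise does not bias RTV medians).
    """

    n_per_arm: Union[int, tuple[int, int]] = (4, 7)
    growth_rate: float = 0.025  # per day
    growth_cv: float = 0.3
    measurement_noise_cv: float = 0.1
    enrollment_window: tuple[float, float] = (60.0, 150.0)
    sacrifice_threshold: float = 500.0
    measurement_interval: int = 7  # days
    max_followup: int = 120  # days
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if isinstance(self.n_per_arm, int):
            lo = hi = self.n_per_arm
        else:
            lo, hi = self.n_per_arm
        if not (1 <= lo <= hi):
            raise ValidationError(f"invalid n_per_arm: {self.n_per_arm}")
        if self.growth_rate < 0 or self.growth_cv < 0 or self.measurement_noise_cv < 0:
            raise ValidationError("rates and CVs must be non-negative")
        low, high = self.enrollment_window
        if not (0 < low <= high < self.sacrifice_threshold):
            raise ValidationError(
                f"enrollment window {self.enrollment_window} must lie within "
                f"(0, {self.sacrifice_threshold})"
            )
        if self.measurement_interval < 1 or self.max_followup < 1:
            raise ValidationError("measurement interval and follow-up must be >= 1 day")

    def draw_arm_size(self, rng: np.random.Generator) -> int:
        if isinstance(self.n_per_arm, int):
            return self.n_per_arm
        lo, hi = self.n_per_arm
        return int(rng.integers(lo, hi + 1))


def simulate_curve(
    config: SimConfig,
    arm_effect: float,
    rng: np.random.Generator,
    mouse_id: str = "m1",
    arm_label: str = "arm",
) -> GrowthCurve:
    """Simulate one mouse's growth curve.

    ``arm_effect`` is the multiplicative growth-rate reduction (0 = control,
    1 = full arrest). Draw order per mouse is fixed (baseline, rate, then
    one noise draw per measurement day) so curves are reproducible from the
    generator state.
    """
    v1 = float(rng.uniform(*config.enrollment_window))
    if config.growth_cv > 0:
        sigma_g = _lognormal_sigma(config.growth_cv)
        g_i = config.growth_rate * math.exp(sigma_g * rng.standard_normal())
    else:
        g_i = config.growth_rate
    rate = g_i * (1.0 - arm_effect)
    sigma_n = _lognormal_sigma(config.measurement_noise_cv)

    measurements: list[TumorMeasurement] = []
    status = ALIVE
    day = 1
    while day <= config.max_followup:
        latent = v1 * math.exp(rate * (day - 1))
        observed = latent
        # day 1 is the enrollment measurement itself: the baseline is the
        # recorded enrollment volume, noise applies to later readings
        if sigma_n > 0 and day > 1:
            observed = latent * math.exp(sigma_n * rng.standard_normal())
        measurements.append(TumorMeasurement(mouse_id, day, observed))
        if observed >= config.sacrifice_threshold:
            status = SACRIFICED
            break
        day += config.measurement_interval
    return GrowthCurve(mouse_id, arm_label, tuple(measurements), status)


def simulate_study(
    config: SimConfig,
    arms: Mapping[str, float],
    seed: Optional[int] = None,
    control_name: str = "control",
) -> Study:
    """Simulate a full randomized study.

    ``arms`` maps arm labels to treatment effects; it must contain
    ``control_name`` (typically with effect 0) plus at least one treated
    arm. Mice are independent; per-mouse random streams are spawned
    deterministically from the single study seed, so the same seed always
    reproduces the same study.
    """
    if control_name not in arms:
        raise ValidationError(f"arms must include the control arm {control_name!r}")
    if len(arms) < 2:
        raise ValidationError("need at least one treated arm besides control")
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    size_rng = np.random.default_rng(root.spawn(1)[0])
    arm_labels = list(arms)
    sizes = {label: config.draw_arm_size(size_rng) for label in arm_labels}
    streams = root.spawn(sum(sizes.values()))

    study_arms: list[StudyArm] = []
    k = 0
    for label in arm_labels:
        effect = arms[label]
        curves = []
        for i in range(sizes[label]):
            rng = np.random.default_rng(streams[k])
            k += 1
            curves.append(
                simulate_curve(config, effect, rng, f"{label}-{i + 1:02d}", label)
            )
        study_arms.append(StudyArm(label, tuple(curves), treatment_label=label))
    return Study(tuple(study_arms), control_name=control_name)


def simulate_ct_table(
    genes: Sequence[str],
    group_shifts: Mapping[str, Union[float, Mapping[str, float]]],
    noise_sd: float = 0.25,
    n_per_group: int = 4,
    seed: Optional[int] = None,
    base_log2_expression: float = -5.0,
    ref_ct_mean: float = 25.0,
    ref_ct_sd: float = 0.5,
) -> list[CtRecord]:
    """Simulate a dual-reference RT-qPCR Ct table.

    For each sample, the two TBP reference transcripts get Ct values drawn
    around ``ref_ct_mean``; each target gene's Ct is

        Ct = Ct_ref_combined − log2(expression) + Normal(0, noise_sd)

    where log2(expression) = ``base_log2_expression`` plus the group's shift
    for that gene (``group_shifts`` values are either a scalar applied to
    all genes or a per-gene mapping; a shift of −1 halves expression). The
    default base of −5 puts targets near Ct 30, inside the quantifiable
    range (basal limit Ct 35).
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    for group, shift in group_shifts.items():
        for i in range(n_per_group):
            sid = f"{group}-s{i + 1:02d}"
            ct_h = float(rng.normal(ref_ct_mean, ref_ct_sd))
            ct_m = float(rng.normal(ref_ct_mean, ref_ct_sd))
            records.append(CtRecord(sid, group, REFERENCE_GENE, ct_h, "human"))
            records.append(CtRecord(sid, group, REFERENCE_GENE, ct_m, "murine"))
            ref = (ct_h + ct_m) / 2.0
            for gene in genes:
                delta = shift if not isinstance(shift, Mapping) else shift.get(gene, 0.0)
                log2_expr = base_log2_expression + float(delta)
                ct = ref - log2_expr
                if noise_sd > 0:
                    ct += float(rng.normal(0.0, noise_sd))
                records.append(CtRecord(sid, group, gene, ct))
    return records
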