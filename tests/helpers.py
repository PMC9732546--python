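"""Shared constructors for hand-built studies used across the test modules."""

from __future__ import annotations

from typing import Optional, Sequence

from pdxefficacy import GrowthCurve, Study, StudyArm, TumorMeasurement


def make_curve(
    volumes: Sequence[float],
    days: Optional[Sequence[int]] = None,
    mouse_id: str = "m1",
    arm: str = "control",
    status: str = "alive-at-study-end",
) -> GrowthCurve:
    """A growth curve from a volume series (weekly days starting at 1 by default)."""
    if days is None:
        days = [1 + 7 * i for i in range(len(volumes))]
    ms = tuple(
        TumorMeasurement(mouse_id, d, v) for d, v in zip(days, volumes)
    )
    return GrowthCurve(mouse_id, arm, ms, status)


def make_arm(
    name: str,
    volume_lists: Sequence[Sequence[float]],
    days: Optional[Sequence[int]] = None,
) -> StudyArm:
    curves = tuple(
        make_curve(v, days, mouse_id=f"{name}-{i + 1}", arm=name)
        for i, v in enumerate(volume_lists)
    )
    return StudyArm(name, curves, treatment_label=name)


def make_study(
    control_volumes: Sequence[Sequence[float]],
    treated_volumes: Sequence[Sequence[float]],
    days: Optional[Sequence[int]] = None,
    treated_name: str = "treated",
) -> Study:
    return Study(
        (
            make_arm("control", control_volumes, days),
            make_arm(treated_name, treated_volumes, days),
        ),
        control_name="control",
    )
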