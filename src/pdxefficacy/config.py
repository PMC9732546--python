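"""Analysis configuration shared by the pipeline, readers and CLI."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis-level policy knobs in one place.

    volume_convention
        How caliper diameters become volumes: ``"as-printed"`` ((a·b)²/2) or
        ``"conventional"`` (a·b²/2). RTV-based metrics are invariant to this
        choice when applied study-wide.
    control_arm
        Name of the control arm in measurement files.
    enrollment_window
        Baseline-volume window (mm³); baselines outside it draw a warning,
        or exclude the mouse when ``enrollment_hard_filter`` is on.
    min_evaluable_per_arm
        Minimum measured mice per arm for a day to enter the TGI series.
    evaluation_day
        Fixed day for responder classification; None = each arm's last
        measurement day shared with control ("end of treatment").
    exact_test_max_n
        Combined sample size at or below which Mann-Whitney uses the exact
        enumeration (tie-free data).
    reference_mode
        qPCR basal normalization reference: ``"per-sample"`` or
        ``"cohort-median"``.
    """

    volume_convention: str = "as-printed"
    control_arm: str = "control"
    enrollment_window: tuple[float, float] = (60.0, 150.0)
    enrollment_hard_filter: bool = False
    min_evaluable_per_arm: int = 2
    evaluation_day: Optional[int] = None
    exact_test_max_n: int = 20
    basal_ct: float = 35.0
    reference_mode: str = "per-sample"

    def __post_init__(self) -> None:
        if self.volume_convention not in ("as-printed", "conventional"):
            raise ValidationError(
                f"unknown volume convention {self.volume_convention!r}"
            )
        if self.reference_mode not in ("per-sample", "cohort-median"):
            raise ValidationError(f"unknown reference mode {self.reference_mode!r}")
        lo, hi = self.enrollment_window
        if not (0 < lo <= hi):
            raise ValidationError(f"bad enrollment window {self.enrollment_window}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enrollment_window"] = list(self.enrollment_window)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a flat key-value config file (YAML mapping of scalars)."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "enrollment_window" in raw:
            raw["enrollment_window"] = tuple(raw["enrollment_window"])
        return cls(**raw)
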