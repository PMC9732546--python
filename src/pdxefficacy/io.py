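"""Readers and writers for the package's two tabular interchange formats.

Measurement CSV (long format, header required)
    mouse_id, arm, day, diameter_a_mm, diameter_b_mm, volume_mm3
    Each row carries either both diameters (volume is then computed with the
    configured convention) or a volume directly. UTF-8, comma-separated,
    '.' decimal.

Ct CSV
    sample_id, group, gene, species_tag, ct
    Reference rows use gene = TBP with species_tag "human" or "murine"; an
    empty ct field means no amplification (undetected).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .config import AnalysisConfig
from .errors import ValidationError
from .growth import GrowthCurve, Study, StudyArm, TumorMeasurement, volume_from_diameters
from .qpcr import CtRecord
from .survival import SurvivalRecord

logger = logging.getLogger("pdxefficacy")

MEASUREMENT_COLUMNS = [
    "mouse_id", "arm", "day", "diameter_a_mm", "diameter_b_mm", "volume_mm3",
]
CT_COLUMNS = ["sample_id", "group", "gene", "species_tag", "ct"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_measurements(path, config: Optional[AnalysisConfig] = None) -> Study:
    """Read and validate a Measurement CSV into a Study.

    Rejects malformed rows, duplicate (mouse, day) pairs and mice whose first
    measurement is not on day 1, naming the offending 1-based data rows.
    Baselines outside the enrollment window are warned about, or the mouse is
    excluded entirely when the config's hard filter is on.
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValidationError(f"{path}: no measurement rows")
    _require_columns(df, MEASUREMENT_COLUMNS, path)

    bad_rows: list[str] = []
    records: list[tuple[str, str, TumorMeasurement]] = []
    for idx, row in df.iterrows():
        rowno = idx + 1
        try:
            mouse = str(row["mouse_id"])
            arm = str(row["arm"])
            day_raw = float(row["day"])
            if not day_raw.is_integer():
                raise ValidationError(f"non-integer day {row['day']}")
            day = int(day_raw)
            a = row["diameter_a_mm"]
            b = row["diameter_b_mm"]
            v = row["volume_mm3"]
            has_diams = pd.notna(a) and pd.notna(b)
            if pd.notna(v):
                volume = float(v)
            elif has_diams:
                volume = volume_from_diameters(
                    float(a), float(b), config.volume_convention
                )
            else:
                raise ValidationError("neither volume nor both diameters given")
            m = TumorMeasurement(
                mouse, day, volume,
                diameter_a=float(a) if has_diams else None,
                diameter_b=float(b) if has_diams else None,
            )
            records.append((mouse, arm, m))
        except (ValidationError, ValueError, TypeError) as exc:
            bad_rows.append(f"row {rowno}: {exc}")
    if bad_rows:
        raise ValidationError(f"{path}: malformed rows:\n  " + "\n  ".join(bad_rows))

    # duplicate (mouse, day) detection with row references
    seen: dict[tuple[str, int], int] = {}
    dups: list[str] = []
    for i, (mouse, _arm, m) in enumerate(records):
        key = (mouse, m.day)
        if key in seen:
            dups.append(f"row {i + 1} duplicates (mouse {mouse!r}, day {m.day})")
        seen[key] = i
    if dups:
        raise ValidationError(f"{path}: duplicate measurements:\n  " + "\n  ".join(dups))

    by_mouse: dict[str, list[TumorMeasurement]] = {}
    mouse_arm: dict[str, str] = {}
    for mouse, arm, m in records:
        if mouse in mouse_arm and mouse_arm[mouse] != arm:
            raise ValidationError(
                f"{path}: mouse {mouse!r} appears in arms "
                f"{mouse_arm[mouse]!r} and {arm!r}"
            )
        mouse_arm[mouse] = arm
        by_mouse.setdefault(mouse, []).append(m)

    curves: dict[str, list[GrowthCurve]] = {}
    lo, hi = config.enrollment_window
    for mouse, ms in by_mouse.items():
        ms.sort(key=lambda m: m.day)
        curve = GrowthCurve(mouse, mouse_arm[mouse], tuple(ms))
        v1 = curve.baseline_volume
        if not (lo <= v1 <= hi):
            if config.enrollment_hard_filter:
                logger.warning(
                    "mouse %s excluded: baseline volume %.1f mm3 outside "
                    "enrollment window [%g, %g]", mouse, v1, lo, hi,
                )
                continue
            logger.warning(
                "mouse %s: baseline volume %.1f mm3 outside enrollment "
                "window [%g, %g]", mouse, v1, lo, hi,
            )
        curves.setdefault(mouse_arm[mouse], []).append(curve)

    if not curves:
        raise ValidationError(f"{path}: no mice left after enrollment filtering")
    arms = tuple(
        StudyArm(name, tuple(sorted(cs, key=lambda c: c.mouse_id)), treatment_label=name)
        for name, cs in sorted(curves.items())
    )
    control = config.control_arm if config.control_arm in curves else arms[0].name
    if control != config.control_arm:
        logger.warning(
            "control arm %r not found; using %r", config.control_arm, control
        )
    return Study(arms, control_name=control)


def write_measurements(study: Study, path) -> None:
    """Write a Study back to the Measurement CSV format (sorted, deterministic)."""
    rows = []
    for arm in study.arms:
        for curve in arm.curves:
            for m in curve.measurements:
                rows.append(
                    {
                        "mouse_id": m.mouse_id,
                        "arm": arm.name,
                        "day": m.day,
                        "diameter_a_mm": m.diameter_a if m.diameter_a is not None else "",
                        "diameter_b_mm": m.diameter_b if m.diameter_b is not None else "",
                        "volume_mm3": repr(m.volume),
                    }
                )
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    df = df.sort_values(["arm", "mouse_id", "day"], kind="mergesort")
    df.to_csv(path, index=False, lineterminator="\n")


def read_ct_table(path) -> list[CtRecord]:
    """Read and validate a Ct CSV. Empty ct fields become undetected (None)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValidationError(f"{path}: no Ct rows")
    _require_columns(df, CT_COLUMNS, path)
    records: list[CtRecord] = []
    bad: list[str] = []
    for idx, row in df.iterrows():
        rowno = idx + 1
        ct_raw = row["ct"]
        try:
            if pd.isna(ct_raw) or (isinstance(ct_raw, str) and not ct_raw.strip()):
                ct = None
            else:
                ct = float(ct_raw)
                if math.isnan(ct):
                    ct = None
            tag = row["species_tag"]
            species = None if pd.isna(tag) or str(tag).strip() == "" else str(tag)
            records.append(
                CtRecord(str(row["sample_id"]), str(row["group"]),
                         str(row["gene"]), ct, species)
            )
        except (ValidationError, ValueError, TypeError) as exc:
            bad.append(f"row {rowno}: {exc}")
    if bad:
        raise ValidationError(f"{path}: malformed rows:\n  " + "\n  ".join(bad))
    return records


def write_ct_table(records: Sequence[CtRecord], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "group": r.group,
            "gene": r.gene,
            "species_tag": r.species_tag or "",
            "ct": repr(r.ct) if r.ct is not None else "",
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=CT_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def write_survival_table(records: Sequence[SurvivalRecord], path) -> None:
    """Export event/censor records: mouse_id, arm, fold, time_days, event (0/1)."""
    rows = [
        {
            "mouse_id": r.mouse_id,
            "arm": r.arm_label,
            "fold": r.fold_threshold,
            "time_days": r.time,
            "event": int(r.event),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["mouse_id", "arm", "fold", "time_days", "event"])
    df = df.sort_values(["fold", "arm", "mouse_id"], kind="mergesort")
    df.to_csv(path, index=False, lineterminator="\n")
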