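"""Relative RT-qPCR quantification with dual-species TBP referencing.

Expression of a target gene is quantified on the 2^dCt scale: with
dCt = Ct(reference) − Ct(target), the relative quantity N_target = 2^dCt.
The reference is the TATA-box binding protein (TBP) transcript measured in
both its human (tumor) and murine (stroma) forms; the two reference Ct
values are combined by their arithmetic mean (the geometric mean of the
linear quantities). Values are then basal-normalized so that a target at the
quantification limit Ct = 35 maps to 1 and each cycle below 35 doubles the
value. Undetected targets (Ct >= 40 or missing) are floored at the basal
level 1 and flagged rather than dropped, preserving sample counts for rank
tests; an exclusion option is available in :func:`compare_expression`.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .errors import BelowQuantificationError, ValidationError
from .stats import TestResult, mann_whitney

__all__ = [
    "CtRecord",
    "ExpressionRecord",
    "delta_ct",
    "combine_references",
    "n_target",
    "basal_normalize",
    "quantify",
    "compare_expression",
    "REFERENCE_GENE",
]

#: gene symbol of the reference transcript
REFERENCE_GENE = "TBP"
#: Ct of the smallest quantifiable amount of target mRNA ("basal mRNA level")
BASAL_CT = 35.0
#: Ct at or above which a target is considered undetected
UNDETECTED_CT = 40.0


@dataclass(frozen=True)
class CtRecord:
    """One raw qPCR cycle-threshold measurement."""

    sample_id: str
    group: str
    gene: str
    ct: Optional[float]  # None = no amplification
    species_tag: Optional[str] = None  # "human"/"murine", used on TBP rows

    def __post_init__(self) -> None:
        if self.ct is not None and not self.ct > 0:
            raise ValidationError(
                f"Ct must be positive, got {self.ct} for {self.sample_id}/{self.gene}"
            )
        if self.gene == REFERENCE_GENE and self.species_tag not in ("human", "murine"):
            raise ValidationError(
                f"reference rows must carry species_tag human or murine, "
                f"got {self.species_tag!r} for sample {self.sample_id}"
            )

    @property
    def is_reference(self) -> bool:
        return self.gene == REFERENCE_GENE

    @property
    def undetected(self) -> bool:
        return self.ct is None or self.ct >= UNDETECTED_CT


@dataclass(frozen=True)
class ExpressionRecord:
    """Relative expression of one gene in one sample.

    ``n_target`` is 2^dCt, or the basal-normalized value when ``normalized``
    is True. ``below_quantification`` marks undetected targets floored at 1.
    """

    sample_id: str
    group: str
    gene: str
    n_target: float
    normalized: bool = False
    below_quantification: bool = False

    def __post_init__(self) -> None:
        if not self.n_target > 0:
            raise ValidationError(f"expression must be positive, got {self.n_target}")


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """dCt = Ct(reference) − Ct(target).

    Positive dCt means the target is more abundant than the reference
    (amplifies earlier).
    """
    if ct_target is None:
        raise BelowQuantificationError("target undetected: no Ct value")
    if ct_reference is None:
        raise ValidationError("reference Ct missing")
    if ct_target >= UNDETECTED_CT:
        raise BelowQuantificationError(
            f"target Ct {ct_target} is at/above the detection limit {UNDETECTED_CT}"
        )
    return ct_reference - ct_target


def combine_references(
    ct_tbp_human: Optional[float], ct_tbp_murine: Optional[float]
) -> float:
    """Combined reference Ct: mean of the available TBP transcripts.

    A single available transcript passes through unchanged; with both absent
    the sample has no usable reference.
    """
    present = [c for c in (ct_tbp_human, ct_tbp_murine) if c is not None]
    if not present:
        raise ValidationError("sample has neither human nor murine TBP reference")
    return sum(present) / len(present)


def n_target(dct: float) -> float:
    """Relative expression 2^dCt (one qPCR cycle = one doubling)."""
    return 2.0**dct


def basal_factor(ct_reference: float, basal_ct: float = BASAL_CT) -> float:
    """Expression a target at the basal Ct would show: 2^(Ct_ref − basal)."""
    return 2.0 ** (ct_reference - basal_ct)


def basal_normalize(
    records: Sequence[ExpressionRecord],
    references: dict[str, float],
    basal_ct: float = BASAL_CT,
) -> list[ExpressionRecord]:
    """Normalize expressions so a target at Ct = ``basal_ct`` maps to 1.

    Each record's 2^dCt value is divided by its sample's basal expression
    2^(Ct_ref − basal_ct); ``references`` maps sample_id to the (combined)
    reference Ct used for that sample.
    """
    out = []
    for r in records:
        if r.normalized:
            raise ValidationError(f"record {r.sample_id}/{r.gene} already normalized")
        ref = references[r.sample_id]
        out.append(
            replace(r, n_target=r.n_target / basal_factor(ref, basal_ct), normalized=True)
        )
    return out


def sample_references(
    records: Iterable[CtRecord], warn: bool = True
) -> dict[str, float]:
    """Combined TBP reference Ct per sample.

    Samples missing both TBP transcripts get no entry (and a warning): they
    cannot be quantified.
    """
    refs: dict[str, dict[str, float]] = {}
    samples: list[str] = []
    for r in records:
        if r.sample_id not in refs:
            refs[r.sample_id] = {}
            samples.append(r.sample_id)
        if r.is_reference and not r.undetected:
            refs[r.sample_id][r.species_tag] = r.ct
    combined: dict[str, float] = {}
    for sid in samples:
        tags = refs[sid]
        if not tags:
            if warn:
                warnings.warn(
                    f"sample {sid!r} has no usable TBP reference; excluded",
                    RuntimeWarning,
                    stacklevel=2,
                )
            continue
        combined[sid] = combine_references(tags.get("human"), tags.get("murine"))
    return combined


def quantify(
    records: Sequence[CtRecord],
    basal_ct: float = BASAL_CT,
    reference_mode: str = "per-sample",
) -> list[ExpressionRecord]:
    """Full relative quantification of a Ct table.

    For each target row: dCt against the sample's combined TBP reference,
    N_target = 2^dCt, then basal normalization. With
    ``reference_mode="cohort-median"`` the normalization divisor uses the
    cohort-median reference Ct for every sample (improves cross-sample
    comparability when reference levels drift); ``"per-sample"`` uses each
    sample's own reference. Undetected targets are floored at 1 and flagged.
    Samples without any TBP reference are dropped with a warning.
    """
    if reference_mode not in ("per-sample", "cohort-median"):
        raise ValidationError(f"unknown reference mode {reference_mode!r}")
    refs = sample_references(records)
    norm_refs = refs
    if reference_mode == "cohort-median" and refs:
        med = float(statistics.median(refs.values()))
        norm_refs = {sid: med for sid in refs}
    out: list[ExpressionRecord] = []
    for r in records:
        if r.is_reference or r.sample_id not in refs:
            continue
        if r.undetected:
            out.append(
                ExpressionRecord(
                    r.sample_id, r.group, r.gene, 1.0,
                    normalized=True, below_quantification=True,
                )
            )
            continue
        raw = ExpressionRecord(
            r.sample_id, r.group, r.gene, n_target(delta_ct(r.ct, refs[r.sample_id]))
        )
        out.extend(basal_normalize([raw], {r.sample_id: norm_refs[r.sample_id]}, basal_ct))
    return out


def _values_for_gene(
    records: Sequence[ExpressionRecord] | Sequence[float],
    gene: Optional[str],
    exclude_flagged: bool,
) -> list[float]:
    vals: list[float] = []
    for r in records:
        if isinstance(r, ExpressionRecord):
            if gene is not None and r.gene != gene:
                continue
            if exclude_flagged and r.below_quantification:
                continue
            vals.append(r.n_target)
        else:
            vals.append(float(r))
    return vals


def compare_expression(
    gene: Optional[str],
    treated: Sequence[ExpressionRecord] | Sequence[float],
    control: Sequence[ExpressionRecord] | Sequence[float],
    exclude_flagged: bool = False,
) -> TestResult:
    """Treated-vs-control Mann–Whitney comparison of one gene's expression.

    Accepts ExpressionRecords (filtered to ``gene``) or raw values. The
    returned result carries the fold change of group medians
    (treated / control) in ``details``. ``exclude_flagged`` drops
    below-quantification samples instead of using their floored value.
    """
    tv = _values_for_gene(treated, gene, exclude_flagged)
    cv = _values_for_gene(control, gene, exclude_flagged)
    if len(tv) < 2 or len(cv) < 2:
        raise ValidationError(
            f"need >= 2 samples per group for gene {gene!r}, got {len(tv)} and {len(cv)}"
        )
    result = mann_whitney(tv, cv)
    fold = float(statistics.median(tv)) / float(statistics.median(cv))
    details = dict(result.details)
    details.update(
        gene=gene,
        fold_change=fold,
        median_treated=float(statistics.median(tv)),
        median_control=float(statistics.median(cv)),
    )
    return TestResult(result.statistic, result.p_two_sided, result.method,
                      result.n_per_group, details)
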