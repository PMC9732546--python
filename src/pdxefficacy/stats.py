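"""Exact nonparametric tests used throughout the efficacy analysis.

Self-contained implementations of the two-tailed Mann–Whitney U test (exact
small-sample null distribution, normal approximation with tie and continuity
corrections otherwise) and Fisher's exact test for 2x2 tables (two-sided by
minimum-likelihood summation). Arm sizes in PDX studies are 4–7 mice, so in
practice every comparison takes the exact path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb, sqrt
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ValidationError

__all__ = ["TestResult", "mann_whitney", "fisher_exact", "compare_orr"]

#: combined sample size at or below which the exact Mann-Whitney null
#: distribution is enumerated (tie-free data only)
EXACT_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p_two_sided: float
    method: str
    n_per_group: tuple[int, ...]
    details: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_two_sided <= 1.0):
            raise ValidationError(f"p-value out of (0, 1]: {self.p_two_sided}")


@lru_cache(maxsize=None)
def _u_counts(m: int, n: int) -> tuple[int, ...]:
    """Null distribution of the Mann-Whitney U statistic.

    ``counts[u]`` is the number of the C(m+n, m) equally likely group
    assignments of tie-free pooled data that yield U = u, built with the
    standard recurrence N(u; m, n) = N(u−n; m−1, n) + N(u; m, n−1).
    """
    table: dict[tuple[int, int], list[int]] = {}
    for mm in range(m + 1):
        for nn in range(n + 1):
            if mm == 0 or nn == 0:
                table[(mm, nn)] = [1]
                continue
            size = mm * nn + 1
            left = table[(mm - 1, nn)]
            down = table[(mm, nn - 1)]
            row = []
            for u in range(size):
                total = 0
                if u - nn >= 0 and u - nn < len(left):
                    total += left[u - nn]
                if u < len(down):
                    total += down[u]
                row.append(total)
            table[(mm, nn)] = row
    return tuple(table[(m, n)])


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """U for the first sample (pairs x>y plus half the tied pairs), via midranks."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    m = len(x)
    u = float(ranks[:m].sum() - m * (m + 1) / 2.0)
    return u, pooled


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = EXACT_MAX_N
) -> TestResult:
    """Two-tailed Mann–Whitney U test.

    U counts pairs (x_i, y_j) with x_i > y_j plus half the tied pairs. With
    combined n <= ``exact_max_n`` and no ties the p-value is exact, from the
    full enumeration of group assignments; the two-sided p is
    min(1, 2 * min(P(U <= u), P(U >= u))). Otherwise the normal
    approximation with midrank tie correction and a 0.5 continuity
    correction is used. Tied data never take the exact path: they fall back
    to the asymptotic method with a warning.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    m, n = len(x), len(y)
    u, pooled = _u_statistic(x, y)
    has_ties = len(np.unique(pooled)) < m + n

    if m + n <= exact_max_n and not has_ties:
        counts = _u_counts(m, n)
        total = comb(m + n, m)
        u_int = int(round(u))
        cum_le = sum(counts[: u_int + 1])
        cum_ge = total - sum(counts[:u_int])
        p = min(1.0, 2.0 * min(cum_le, cum_ge) / total)
        return TestResult(u, p, "exact", (m, n))

    if has_ties and m + n <= exact_max_n:
        warnings.warn(
            "ties present: exact Mann-Whitney enumeration is not valid, "
            "falling back to the tie-corrected normal approximation",
            RuntimeWarning,
            stacklevel=2,
        )

    # asymptotic path with tie correction and continuity correction
    N = m + n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        warnings.warn(
            "zero variance (all pooled values identical); p-value set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return TestResult(u, 1.0, "asymptotic", (m, n))
    z = max(0.0, abs(u - m * n / 2.0) - 0.5) / sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return TestResult(u, p, "asymptotic", (m, n))


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Fisher's exact test on a 2x2 contingency table.

    Two-sided p-value by minimum-likelihood summation: the sum of the
    hypergeometric probabilities, over all tables with the observed margins,
    that are no more probable than the observed table. Probabilities are
    compared as exact integer numerators (C(r1,k)·C(r2,c1−k)), so ties are
    resolved without floating-point ambiguity.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t != np.floor(t)) or np.any(t < 0):
        raise ValidationError(f"table entries must be non-negative integers: {t.tolist()}")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n_total = a + b + c + d
    if n_total == 0:
        raise ValidationError("table total must be positive")
    r1, r2 = a + b, c + d
    c1 = a + c
    denom = comb(n_total, c1)
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    obs_num = comb(r1, a) * comb(r2, c1 - a)
    p_num = sum(
        num
        for k in range(lo, hi + 1)
        if (num := comb(r1, k) * comb(r2, c1 - k)) <= obs_num
    )
    p = min(1.0, p_num / denom)
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return TestResult(odds, p, "exact", (r1, r2), details={"table": t.tolist()})


def compare_orr(table: Sequence[Sequence[int]]) -> TestResult:
    """Compare responder counts of two treatments.

    ``table`` rows are treatments, columns (responders, non-responders);
    delegates to :func:`fisher_exact`.
    """
    return fisher_exact(table)
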