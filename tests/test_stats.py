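"""Oracle-validated tests of the exact Mann-Whitney and Fisher implementations.

The oracles are brute force and independent of the implementations: full
enumeration of group assignments for Mann-Whitney, exact rational
hypergeometric summation for Fisher. scipy acts as an additional external
cross-check on hand-picked cases.
"""

import warnings
from fractions import Fraction
from itertools import combinations
from math import comb, factorial

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from pdxefficacy import ValidationError, compare_orr, fisher_exact, mann_whitney


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def mw_enumeration_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of assignments."""
    pooled = list(x) + list(y)
    m = len(x)
    idx_all = set(range(len(pooled)))
    u_obs = sum(xi > yj for xi in x for yj in y)
    us = []
    for chosen in combinations(range(len(pooled)), m):
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx_all - set(chosen)]
        us.append(sum(xi > yj for xi in xs for yj in ys))
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def fisher_fraction_p(a, b, c, d):
    """Two-sided Fisher p by exact rational hypergeometric summation."""
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d

    def prob(x):
        y = c1 - x
        return Fraction(
            factorial(r1) * factorial(r2) * factorial(c1) * factorial(n - c1),
            factorial(n) * factorial(x) * factorial(r1 - x)
            * factorial(y) * factorial(r2 - y),
        )

    lo, hi = max(0, c1 - r2), min(c1, r1)
    p_obs = prob(a)
    return float(sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_complete_separation_small(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(0.10)
        assert res.method == "exact"

    def test_interleaved_pair(self):
        res = mann_whitney([1, 3], [2, 4])
        assert res.statistic == 1.0
        assert res.p_two_sided == pytest.approx(2 / 3)

    def test_identical_multisets_p_one(self):
        with pytest.warns(RuntimeWarning):
            res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_two_sided == 1.0
        assert res.method == "asymptotic"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    def test_matches_enumeration_oracle_random_cases(self):
        rng = np.random.default_rng(20240101)
        for m in range(1, 8):
            for n in range(1, 9 - m):
                for _ in range(4):
                    x = rng.normal(size=m)
                    y = rng.normal(size=n)
                    res = mann_whitney(list(x), list(y))
                    assert res.method == "exact"
                    assert res.p_two_sided == pytest.approx(
                        mw_enumeration_p(x, y), abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            x = rng.normal(size=int(rng.integers(2, 8)))
            y = rng.normal(size=int(rng.integers(2, 8)))
            ours = mann_whitney(list(x), list(y))
            ref = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="exact")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-10)

    def test_asymptotic_matches_scipy_on_large_samples(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=30)
        y = rng.normal(0.4, size=25)
        ours = mann_whitney(list(x), list(y))
        ref = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic")
        assert ours.method == "asymptotic"
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=6).map(
            lambda v: [x + i * 1e-6 for i, x in enumerate(v)]),
        st.lists(st.integers(0, 50), min_size=2, max_size=6).map(
            lambda v: [x + 51 + i * 1e-6 for i, x in enumerate(v)]),
    )
    def test_label_swap_invariance(self, x, y):
        r1 = mann_whitney(x, y)
        r2 = mann_whitney(y, x)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided, abs=1e-12)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(99)
        x = list(rng.normal(size=5))
        y = list(rng.normal(size=6))
        base = mann_whitney(x, y)
        trans = mann_whitney(list(np.exp(x)), list(np.exp(y)))
        assert trans.statistic == base.statistic
        assert trans.p_two_sided == base.p_two_sided

    def test_ties_fall_back_to_asymptotic_with_warning(self):
        with pytest.warns(RuntimeWarning, match="ties"):
            res = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0])
        assert res.method == "asymptotic"


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_antidiagonal_table(self):
        res = fisher_exact([[0, 5], [5, 0]])
        assert res.p_two_sided == pytest.approx(2 / 252, abs=1e-15)

    def test_balanced_table_p_one(self):
        assert fisher_exact([[1, 1], [1, 1]]).p_two_sided == 1.0

    @given(st.tuples(*(st.integers(0, 12),) * 4).filter(lambda t: sum(t) > 0))
    def test_transpose_symmetry(self, t):
        a, b, c, d = t
        p1 = fisher_exact([[a, b], [c, d]]).p_two_sided
        p2 = fisher_exact([[a, c], [b, d]]).p_two_sided
        assert p1 == pytest.approx(p2, abs=1e-12)

    @given(st.tuples(*(st.integers(0, 10),) * 4).filter(lambda t: sum(t) > 0))
    def test_row_swap_symmetry(self, t):
        a, b, c, d = t
        p1 = fisher_exact([[a, b], [c, d]]).p_two_sided
        p2 = fisher_exact([[c, d], [a, b]]).p_two_sided
        assert p1 == pytest.approx(p2, abs=1e-12)

    @pytest.mark.parametrize(
        "table",
        [
            [[0, 5], [5, 0]], [[3, 13], [3, 13]], [[5, 12], [3, 13]],
            [[1, 9], [11, 3]], [[0, 0], [4, 7]], [[8, 2], [1, 5]],
        ],
    )
    def test_matches_scipy(self, table):
        ours = fisher_exact(table).p_two_sided
        ref = scipy.stats.fisher_exact(table, alternative="two-sided").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_matches_fraction_oracle_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            ours = fisher_exact([[a, b], [c, d]]).p_two_sided
            assert ours == pytest.approx(fisher_fraction_p(a, b, c, d), abs=1e-13)

    @pytest.mark.parametrize(
        "table", [[[-1, 2], [3, 4]], [[1.5, 2], [3, 4]]]
    )
    def test_invalid_counts_rejected(self, table):
        with pytest.raises(ValidationError):
            fisher_exact(table)

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact([[0, 0], [0, 0]])


class TestCompareOrr:
    def test_identical_proportions(self):
        assert compare_orr([[3, 13], [3, 13]]).p_two_sided == 1.0

    def test_extreme_separation(self):
        res = compare_orr([[0, 10], [10, 0]])
        assert res.p_two_sided == pytest.approx(2 / comb(20, 10), rel=1e-12)

    def test_moderate_difference_not_significant(self):
        # 5/17 vs 3/16 responders: clearly compatible proportions
        res = compare_orr([[5, 12], [3, 13]])
        assert res.p_two_sided > 0.05
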