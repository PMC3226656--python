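"""Unit and property tests for the contingency-table layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cdhtest.core import (
    MISSING,
    DegenerateDataError,
    GenotypeVector,
    InputError,
    PhenotypeVector,
    cochran_armitage_trend,
    cross_tabulate,
    fisher_exact_2x2,
    pearson_chi2,
    single_snp_2df,
)


class TestGenotypeVector:
    def test_minor_allele_orientation(self):
        g = GenotypeVector([2, 2, 2, 1, 2, 0])
        assert g.maf == pytest.approx((2 * 1 + 1) / 12)  # flipped
        assert list(g.values) == [0, 0, 0, 1, 0, 2]

    def test_maf_consistent_with_values(self):
        g = GenotypeVector([0, 1, 2, MISSING, 0])
        obs = g.values[g.values != MISSING]
        assert abs(g.maf - obs.mean() / 2) < 1e-12

    def test_nan_becomes_missing(self):
        g = GenotypeVector(np.array([0.0, np.nan, 2.0]))
        assert list(g.values) == [0, MISSING, 2]

    def test_invalid_dosage_rejected(self):
        with pytest.raises(InputError):
            GenotypeVector([0, 3, 1])

    def test_tie_at_half_keeps_input_orientation(self):
        g = GenotypeVector([0, 2, 0, 2])
        assert list(g.values) == [0, 2, 0, 2]


def test_phenotype_requires_both_classes():
    with pytest.raises(DegenerateDataError):
        PhenotypeVector([1, 1, MISSING])
    y = PhenotypeVector([0, 1, MISSING])
    assert y.n_cases == 1


class TestCrossTabulate:
    def test_direct_count_example(self):
        pc = cross_tabulate(
            GenotypeVector([0, 1, 2]),
            GenotypeVector([0, 1, 0]),
            PhenotypeVector([0, 1, 1]),
        )
        assert pc.D[1, 1] == 1 and pc.D[2, 0] == 1
        assert pc.U[0, 0] == 1
        assert pc.D.sum() == 2 and pc.U.sum() == 1

    def test_all_phenotypes_missing_is_degenerate(self):
        g = GenotypeVector([0, 1])
        with pytest.raises(DegenerateDataError):
            PhenotypeVector([MISSING, MISSING])

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            cross_tabulate(
                GenotypeVector([0, 1]),
                GenotypeVector([0, 1, 2]),
                PhenotypeVector([0, 1]),
            )

    def test_conservation_against_direct_count(self, rng):
        """Totals equal the usable sample count (independent loop oracle)."""
        n = 1000
        g1 = GenotypeVector(rng.binomial(2, 0.05, n))
        g2 = GenotypeVector(rng.binomial(2, 0.05, n))
        y = PhenotypeVector(rng.integers(0, 2, n))
        pc = cross_tabulate(g1, g2, y)
        assert pc.total == n
        # independent oracle: per-cell python loop
        for i in range(3):
            for j in range(3):
                expect = sum(
                    1
                    for a, b, c in zip(g1.values, g2.values, y.values)
                    if a == i and b == j and c == 1
                )
                assert pc.D[i, j] == expect


class TestPearsonChi2:
    def test_perfect_independence(self):
        res = pearson_chi2([[10, 10], [10, 10]])
        assert res.statistic == 0 and res.p == 1 and res.df == 1

    def test_hand_evaluated_2x2(self):
        # closed form n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b, c, d = 20, 5, 10, 25
        expect = 60 * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        res = pearson_chi2([[a, b], [c, d]])
        assert res.statistic == pytest.approx(expect)
        assert res.statistic == pytest.approx(15.43, abs=0.005)
        assert res.df == 1

    def test_empty_column_dropped_reduces_df(self):
        res = pearson_chi2([[5, 0, 7], [3, 0, 9]])
        assert res.df == 1

    def test_fewer_than_two_columns_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pearson_chi2([[5, 0], [9, 0]])

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=4, max_size=4)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_closed_form_on_2x2(self, cells):
        a, b, c, d = cells
        t = np.array([[a, b], [c, d]], dtype=float)
        if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
            with pytest.raises(DegenerateDataError):
                pearson_chi2(t)
            return
        n = t.sum()
        expect = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert pearson_chi2(t).statistic == pytest.approx(expect, rel=1e-12, abs=1e-12)


def _fisher_enumeration(table):
    """Brute-force two-sided Fisher P: sum hypergeometric probabilities of
    all margin-consistent tables no more probable than the observed one."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    probs = []
    for aa in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = (
            math.comb(r1, aa)
            * math.comb(n - r1, c1 - aa)
            / math.comb(n, c1)
        )
        probs.append((aa, p))
    p_obs = dict(probs)[a]
    return sum(p for _, p in probs if p <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_diagonal_table(self):
        res = fisher_exact_2x2([[0, 5], [5, 0]])
        assert res.p == pytest.approx(2 / 252)
        assert res.method == "fisher_exact"

    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]).p == 1

    def test_negative_entries_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_2x2([[1, -1], [1, 1]])

    @given(
        st.lists(st.integers(min_value=0, max_value=12), min_size=4, max_size=4)
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_hypergeometric_enumeration(self, cells):
        t = [[cells[0], cells[1]], [cells[2], cells[3]]]
        assert fisher_exact_2x2(t).p == pytest.approx(
            _fisher_enumeration(t), rel=1e-9, abs=1e-12
        )


class TestSingleSnp2df:
    def test_no_association_statistic_zero(self):
        # identical case fraction (5%) in each genotype class
        g2 = GenotypeVector(
            [0] * 450 + [1] * 45 + [2] * 5 + [0] * 8550 + [1] * 855 + [2] * 95
        )
        y2 = PhenotypeVector([1] * 500 + [0] * 9500)
        res = single_snp_2df(g2, y2)
        assert res.statistic == pytest.approx(0, abs=1e-10)
        assert res.df == 2

    def test_single_class_genotype_degenerate(self):
        with pytest.raises(DegenerateDataError):
            single_snp_2df(GenotypeVector([1, 1, 1, 1]), PhenotypeVector([0, 1, 0, 1]))

    def test_equals_pearson_of_tabulation(self, rng):
        g = GenotypeVector(rng.integers(0, 3, 500))
        y = PhenotypeVector(rng.integers(0, 2, 500))
        table = np.zeros((2, 3))
        for d, s in zip(g.values, y.values):
            table[1 - s, d] += 1
        assert single_snp_2df(g, y).statistic == pytest.approx(
            pearson_chi2(table).statistic
        )

    def test_p_uniform_under_permutation(self, rng):
        """Null calibration: permutation distribution of the 2-df P is
        uniform within KS tolerance."""
        n = 2000
        g = GenotypeVector(rng.binomial(2, 0.3, n))
        y0 = rng.random(n) < 0.3
        ps = np.empty(10_000)
        for i in range(ps.size):
            y = PhenotypeVector(rng.permutation(y0).astype(np.int8))
            ps[i] = single_snp_2df(g, y).p
        d = stats.ks_1samp(ps, stats.uniform.cdf).statistic
        assert d < 0.03


class TestCochranArmitage:
    def test_null_statistic_zero(self):
        g = GenotypeVector([0, 0, 1, 1, 2, 2, 0, 0, 1, 1, 2, 2])
        y = PhenotypeVector([1, 0] * 6)
        assert cochran_armitage_trend(g, y).statistic == pytest.approx(0)

    def test_perfect_separation(self):
        g = GenotypeVector([2] * 10 + [0] * 10)
        y = PhenotypeVector([1] * 10 + [0] * 10)
        res = cochran_armitage_trend(g, y)
        assert res.p < 1e-4
        assert res.df == 1

    def test_zero_genotype_variance(self):
        with pytest.raises(DegenerateDataError):
            cochran_armitage_trend(
                GenotypeVector([1, 1, 1, 1]), PhenotypeVector([0, 1, 0, 1])
            )

    def test_equals_score_test_identity(self, rng):
        """Independent oracle: the trend statistic equals N * pearson_r^2
        between dosage and status."""
        g = GenotypeVector(rng.integers(0, 3, 400))
        y = PhenotypeVector(rng.integers(0, 2, 400))
        r = stats.pearsonr(g.values.astype(float), y.values.astype(float)).statistic
        assert cochran_armitage_trend(g, y).statistic == pytest.approx(400 * r * r)
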