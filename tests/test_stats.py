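"""Statistical kernels against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircomplex import (
    DomainError,
    UndefinedCorrelationError,
    adjust_pvalues,
    fisher_exact_greater,
    hypergeom_tail_geq,
    ks_one_sided,
    pearson_correlation,
    permutation_pvalue,
    wilcoxon_signed_rank,
)


def hypergeom_tail_enumerated(k: int, K: int, n: int, N: int) -> float:
    """Oracle: enumerate every n-subset of an N-universe with K marked items."""
    marked = set(range(K))
    total = hits = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        hits += sum(1 for i in subset if i in marked) >= k
    return hits / total


class TestHypergeomTail:
    def test_matches_subset_enumeration_small(self):
        for N in (6, 8, 10):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        expected = hypergeom_tail_enumerated(k, K, n, N)
                        got = hypergeom_tail_geq(k, K, n, N)
                        assert got == pytest.approx(expected, abs=1e-12), (k, K, n, N)

    def test_worked_example(self):
        # P(X >= 3) drawing 5 from 10 with 4 marked = 11/42
        assert hypergeom_tail_geq(3, 4, 5, 10) == pytest.approx(11 / 42, rel=1e-12)

    def test_tail_from_zero_is_one(self):
        assert hypergeom_tail_geq(0, 4, 5, 10) == 1.0

    def test_degenerate_universe(self):
        assert hypergeom_tail_geq(5, 5, 5, 5) == 1.0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            hypergeom_tail_geq(5, 4, 5, 10)  # k > K
        with pytest.raises(DomainError):
            hypergeom_tail_geq(1, 11, 5, 10)  # K > N
        with pytest.raises(DomainError):
            hypergeom_tail_geq(1, 4, 11, 10)  # n > N

    def test_no_underflow_deep_tail(self):
        p = hypergeom_tail_geq(90, 100, 100, 2000)
        assert 0.0 < p < 1e-100


class TestFisherGreater:
    def test_identity_with_hypergeometric_tail(self):
        res = fisher_exact_greater(3, 1, 2, 4)
        assert res.p_value == pytest.approx(11 / 42, rel=1e-12)
        assert res.p_value == pytest.approx(hypergeom_tail_geq(3, 4, 5, 10))

    def test_zero_cell_gives_one(self):
        assert fisher_exact_greater(0, 3, 5, 7).p_value == 1.0

    def test_monotone_decreasing_in_d(self):
        previous = 1.1
        for d in range(1, 51):
            p = fisher_exact_greater(3, 1, 2, d).p_value
            assert p < previous
            previous = p

    def test_agrees_with_scipy(self):
        from scipy.stats import fisher_exact

        for table in [(3, 1, 2, 4), (5, 0, 2, 9), (2, 7, 4, 1)]:
            a, b, c, d = table
            expected = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert fisher_exact_greater(a, b, c, d).p_value == pytest.approx(expected)

    def test_negative_count_rejected(self):
        with pytest.raises(DomainError):
            fisher_exact_greater(-1, 1, 1, 1)


class TestAdjustPvalues:
    def test_holm_step_down_by_hand(self):
        # 3*0.01, max(0.03, 2*0.02), max(0.04, 1*0.03)
        assert adjust_pvalues([0.01, 0.02, 0.03], "holm", m=3) == pytest.approx(
            [0.03, 0.04, 0.04]
        )

    def test_bonferroni_scalar_multiply(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "bonferroni", m=3) == pytest.approx(
            [0.03, 0.06, 0.09]
        )

    def test_family_of_one_is_identity(self):
        assert adjust_pvalues([0.123], "holm", m=1) == pytest.approx([0.123])
        assert adjust_pvalues([0.123], "bonferroni", m=1) == pytest.approx([0.123])

    def test_family_larger_than_tests(self):
        # unmaterialised tests still scale the multiplier (clipped at 1)
        assert adjust_pvalues([0.01], "bonferroni", m=677) == [1.0]
        assert adjust_pvalues([0.001], "holm", m=677) == pytest.approx([0.677])

    def test_m_smaller_than_tests_rejected(self):
        with pytest.raises(DomainError):
            adjust_pvalues([0.1, 0.2], "holm", m=1)

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=12),
        st.integers(0, 10),
    )
    def test_holm_never_exceeds_bonferroni(self, p, extra):
        m = len(p) + extra
        holm = adjust_pvalues(p, "holm", m=m)
        bonf = adjust_pvalues(p, "bonferroni", m=m)
        assert all(h <= b + 1e-12 for h, b in zip(holm, bonf))

    def test_agrees_with_statsmodels_at_m_equals_len(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.04, 0.001, 0.2, 0.8, 0.03]
        assert adjust_pvalues(p, "holm") == pytest.approx(
            list(multipletests(p, method="holm")[1])
        )


def ks_oracle(a, b, alternative):
    """Oracle: sweep ECDF difference over every sample point."""
    points = sorted(set(a) | set(b))
    best = -2.0
    for x in points:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        diff = fa - fb if alternative == "a_less" else fb - fa
        best = max(best, diff)
    return best


class TestKSOneSided:
    def test_identical_samples(self):
        res = ks_one_sided([1, 2, 3], [1, 2, 3], "a_less")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_disjoint_supports(self):
        res = ks_one_sided([1, 2, 3], [11, 12, 13], "a_less")
        assert res.statistic == 1.0

    def test_statistic_matches_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            a = list(rng.normal(0, 1, 20))
            b = list(rng.normal(0.5, 1.3, 20))
            for alt in ("a_less", "a_greater"):
                res = ks_one_sided(a, b, alt)
                assert res.statistic == pytest.approx(ks_oracle(a, b, alt), abs=1e-12)

    def test_asymptotic_p_formula(self):
        a, b = [0.1, 0.4, 0.9], [0.2, 0.5, 1.4, 2.0]
        res = ks_one_sided(a, b, "a_less")
        d = res.statistic
        assert res.p_value == pytest.approx(math.exp(-2 * 3 * 4 * d * d / 7))

    @pytest.mark.parametrize("transform", [lambda x: 3 * x + 1, math.exp])
    def test_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(3)
        a = list(rng.normal(0, 1, 15))
        b = list(rng.normal(0.3, 1, 12))
        base = ks_one_sided(a, b, "a_less")
        moved = ks_one_sided([transform(x) for x in a], [transform(x) for x in b], "a_less")
        assert moved.statistic == pytest.approx(base.statistic)
        assert moved.p_value == pytest.approx(base.p_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            ks_one_sided([], [1.0], "a_less")


def wilcoxon_oracle_greater(diffs):
    """Oracle: exact p over all 2^n sign assignments (average ranks)."""
    from scipy.stats import rankdata

    ranks = rankdata([abs(d) for d in diffs])
    observed = sum(r for d, r in zip(diffs, ranks) if d > 0)
    n = len(diffs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        count += w >= observed
    return count / 2 ** n


class TestWilcoxonSignedRank:
    def test_all_positive_distinct_margins(self):
        pairs = [(i + 1 + 0.1 * (i + 1), i + 1) for i in range(8)]  # 8 positive diffs
        res = wilcoxon_signed_rank(pairs, "greater")
        assert res.p_value == pytest.approx(1 / 2 ** 8)

    def test_exact_matches_sign_enumeration(self):
        rng = np.random.default_rng(11)
        obs = rng.normal(0.3, 1, 10)
        ref = rng.normal(0, 1, 10)
        res = wilcoxon_signed_rank(list(zip(obs, ref)), "greater")
        assert res.p_value == pytest.approx(wilcoxon_oracle_greater(list(obs - ref)))

    def test_antisymmetric_differences_two_sided(self):
        # differences  +-d in mirror pairs: statistic at its null mean
        diffs = [1, -1, 2, -2, 3, -3, 4, -4]
        pairs = [(d, 0.0) for d in diffs]
        res = wilcoxon_signed_rank(pairs, "two-sided")
        assert res.p_value > 0.9

    def test_all_zero_differences_rejected(self):
        with pytest.raises(DomainError):
            wilcoxon_signed_rank([(1.0, 1.0)] * 8, "greater")

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DomainError):
            wilcoxon_signed_rank([(2.0, 1.0)] * 5, "greater")


class TestPermutationPvalue:
    def test_add_one_floor(self):
        nulls = list(range(1000))
        assert permutation_pvalue(2000.0, nulls) == pytest.approx(1 / 1001)

    def test_direct_count(self):
        assert permutation_pvalue(2.5, [1, 2, 3, 4]) == pytest.approx(3 / 5)

    def test_median_observation(self):
        rng = np.random.default_rng(0)
        nulls = list(rng.normal(size=999))
        p = permutation_pvalue(float(np.median(nulls)), nulls)
        assert abs(p - 0.5) < 0.01

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(-100, 100),
        st.lists(st.floats(-100, 100), min_size=1, max_size=50),
    )
    def test_range_invariant(self, obs, nulls):
        p = permutation_pvalue(obs, nulls)
        assert 1 / (len(nulls) + 1) <= p <= 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(DomainError):
            permutation_pvalue(1.0, [])


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_direct_formula(self):
        x = [1.0, 2.0, 4.0, 5.0, 9.0]
        y = [2.0, 1.0, 5.0, 3.0, 8.0]
        mx, my = sum(x) / 5, sum(y) / 5
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sx = math.sqrt(sum((a - mx) ** 2 for a in x))
        sy = math.sqrt(sum((b - my) ** 2 for b in y))
        assert pearson_correlation(x, y) == pytest.approx(cov / (sx * sy))

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
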