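"""Frequencies, heterozygosities, F_IS and the exact HWE test.

The Monte-Carlo HWE test is validated against an exhaustive enumeration of
all perfect matchings of the gene copies for small N (the exact conditional
null distribution).
"""

import itertools

import numpy as np
import pytest

from bolapop import (
    DiversityStats,
    ValidationError,
    allele_frequencies,
    diversity_stats,
    expected_heterozygosity_unbiased,
    f_is,
    hwe_exact_test,
    ml_standard_error,
    observed_heterozygosity,
    shared_allele_summary,
    size_effect_correlation,
)

from conftest import make_table


def enumerate_matchings(copies):
    """All perfect matchings of distinguishable gene copies; yields the
    heterozygosity of each induced genotype table (brute-force oracle for
    the permutation null)."""
    copies = list(copies)
    if not copies:
        yield 0
        return
    first, rest = copies[0], copies[1:]
    for i in range(len(rest)):
        partner = rest[i]
        remaining = rest[:i] + rest[i + 1 :]
        for het in enumerate_matchings(remaining):
            yield het + (first != partner)


def exact_deficit_p(copies, h_obs):
    """Exact Pr(h_perm <= h_obs) over all equally likely matchings."""
    n_pairs = len(copies) // 2
    hets = [het / n_pairs for het in enumerate_matchings(copies)]
    return sum(1 for h in hets if h <= h_obs + 1e-12) / len(hets)


class TestFrequencies:
    def test_direct_counting_and_ml_se(self):
        g = make_table([("A", "B")] * 25 + [("A", "A")] * 25)
        ft = allele_frequencies(g, "p1")
        assert ft.alleles["A"].count == 75 and ft.alleles["B"].count == 25
        assert ft.alleles["B"].p == pytest.approx(0.25)
        # p=0.5 at N=50 has se sqrt(0.25/100) = 0.05
        assert ml_standard_error(0.5, 50) == pytest.approx(0.05)

    def test_se_zero_at_fixation(self):
        assert ml_standard_error(0.0, 10) == 0.0
        assert ml_standard_error(1.0, 10) == 0.0

    def test_se_maximal_at_half(self):
        ps = np.linspace(0.01, 0.99, 99)
        ses = [ml_standard_error(p, 30) for p in ps]
        assert np.argmax(ses) == 49

    def test_published_cohort_se(self):
        # allele at p=0.117 in a cohort of N=60 has ML standard error 0.029
        assert ml_standard_error(0.117, 60) == pytest.approx(0.029, abs=5e-4)

    def test_unknown_population_rejected(self, tiny_table):
        with pytest.raises(ValidationError):
            allele_frequencies(tiny_table, "nope")


class TestSharedAlleles:
    def test_identical_single_allele_populations(self):
        shared, mc = shared_allele_summary({"a": 1.0}, {"a": 1.0})
        assert shared == {"a"} and mc == pytest.approx(1.0)

    def test_disjoint_sets(self):
        shared, mc = shared_allele_summary({"a": 1.0}, {"b": 1.0})
        assert shared == set() and mc == 0.0

    def test_mean_cumulative_is_mean_of_per_population_sums(self):
        fa = {"a": 0.5, "b": 0.3, "c": 0.2}
        fb = {"a": 0.1, "b": 0.1, "d": 0.8}
        shared, mc = shared_allele_summary(fa, fb)
        assert shared == {"a", "b"}
        assert mc == pytest.approx((0.8 + 0.2) / 2)


class TestHeterozygosity:
    def test_observed_counts_heterozygotes(self, tiny_table):
        assert observed_heterozygosity(tiny_table, "p1") == pytest.approx(0.5)
        assert observed_heterozygosity(make_table([("A", "A")] * 3), "p1") == 0.0
        assert observed_heterozygosity(make_table([("A", "B")] * 2), "p1") == 1.0

    def test_expected_unbiased_small_sample(self):
        g = make_table([("A", "B"), ("A", "B")])
        ft = allele_frequencies(g, "p1")
        # N=2, p=(0.5,0.5): (4/3) * 0.5
        assert expected_heterozygosity_unbiased(ft) == pytest.approx(2 / 3, abs=1e-4)

    def test_expected_approaches_gene_diversity_for_large_n(self):
        g = make_table([("A", "B")] * 5000)
        ft = allele_frequencies(g, "p1")
        assert expected_heterozygosity_unbiased(ft) == pytest.approx(0.5, abs=1e-3)

    def test_monomorphic_zero(self):
        ft = allele_frequencies(make_table([("A", "A")] * 4), "p1")
        assert expected_heterozygosity_unbiased(ft) == 0.0


class TestFis:
    def test_hand_value(self, tiny_table):
        fis, _p = f_is(tiny_table, "p1", n_perm=200, seed=1)
        # h_o = 0.5, unbiased h_e = (8/7) * 0.5 = 0.5714
        assert fis == pytest.approx(1 - 0.5 / (8 / 7 * 0.5), abs=1e-9)
        assert fis == pytest.approx(0.125, abs=5e-4)

    def test_zero_when_observed_equals_expected(self):
        # crafted so h_o == unbiased h_e is impossible exactly; check sign
        # symmetry instead: excess heterozygotes give negative F_IS
        g = make_table([("A", "B")] * 10)
        fis, _ = f_is(g, "p1", n_perm=200, seed=1)
        assert fis < 0

    def test_monomorphic_flagged(self):
        g = make_table([("A", "A")] * 4)
        with pytest.raises(ValidationError):
            f_is(g, "p1", n_perm=200, seed=1)
        st = diversity_stats(g, "p1", n_perm=200, seed=1)
        assert st.f_is is None and st.hwe_p is None and st.n_a == 1


class TestHweExactTest:
    def test_matches_exhaustive_enumeration_small_n(self):
        cases = [
            [("A", "A"), ("A", "B"), ("B", "B")],
            [("A", "A"), ("B", "B"), ("A", "B"), ("A", "B")],
            [("A", "A"), ("A", "A"), ("B", "B"), ("A", "B"), ("C", "C")],
            [("A", "B"), ("A", "C"), ("B", "C"), ("A", "A")],
        ]
        for genos in cases:
            g = make_table(genos)
            copies = [al for a, b in genos for al in (a, b)]
            h_obs = observed_heterozygosity(g, "p1")
            exact = exact_deficit_p(copies, h_obs)
            mc = hwe_exact_test(g, "p1", n_perm=20_000, seed=3)
            assert mc == pytest.approx(exact, abs=0.02), genos

    def test_extreme_deficit_detected(self):
        g = make_table([("A", "A")] * 10 + [("B", "B")] * 10)
        p = hwe_exact_test(g, "p1", n_perm=10_000, seed=5)
        assert p < 0.01

    def test_deterministic_given_seed(self, tiny_table):
        p1 = hwe_exact_test(tiny_table, "p1", n_perm=100, seed=9)
        p2 = hwe_exact_test(tiny_table, "p1", n_perm=100, seed=9)
        assert p1 == p2

    def test_valid_and_nondegenerate_under_null(self):
        """Under random mating the test's p-values are (conservatively)
        valid -- P(p <= a) <= a plus Monte-Carlo slack -- and still spread
        over (0, 1), not piled near 0 or 1."""
        rng = np.random.default_rng(0)
        ps = []
        for s in range(120):
            copies = rng.integers(0, 2, size=120)
            genos = [("AB"[copies[2 * i]], "AB"[copies[2 * i + 1]]) for i in range(60)]
            ps.append(hwe_exact_test(make_table(genos), "p1", n_perm=1000, seed=int(s)))
        ps = np.array(ps)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            assert np.mean(ps <= alpha) <= alpha + 0.08
        assert np.mean(ps <= 0.6) > 0.3

    def test_too_few_permutations_rejected(self, tiny_table):
        with pytest.raises(ValidationError):
            hwe_exact_test(tiny_table, "p1", n_perm=10, seed=0)


class TestSizeEffect:
    @staticmethod
    def _stats(pairs):
        return [
            DiversityStats(f"p{i}", n, 2, h, h, None, None, None)
            for i, (n, h) in enumerate(pairs)
        ]

    def test_pearson_r(self):
        stats = self._stats([(10, 0.2), (20, 0.4), (30, 0.6), (40, 0.8)])
        assert size_effect_correlation(stats, "h_o") == pytest.approx(1.0)

    def test_constant_field_rejected(self):
        stats = self._stats([(10, 0.5), (20, 0.5), (30, 0.5)])
        with pytest.raises(ValidationError):
            size_effect_correlation(stats, "h_o")

    def test_needs_three_populations(self):
        stats = self._stats([(10, 0.2), (20, 0.4)])
        with pytest.raises(ValidationError):
            size_effect_correlation(stats, "h_e")
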