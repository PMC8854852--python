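"""PBR identity/similarity, amino-acid profiles, correlation and UPGMA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bolapop import (
    PBRMask,
    PBRProfile,
    SimulationConfig,
    ValidationError,
    pair_identity_similarity,
    pbr_profile,
    population_similarity,
    profile_correlation,
    simulate_metapopulation,
    upgma,
)
from bolapop.io_model import AMINO_ACIDS, AlleleSequenceSet, PairwiseMatrix

from conftest import make_table


class TestPairIdentitySimilarity:
    def test_identical(self):
        assert pair_identity_similarity("ACDE", "ACDE") == (100.0, 100.0)

    def test_conservative_change_counts_as_similar(self):
        ident, simil = pair_identity_similarity("ACD", "ACE")
        assert ident == pytest.approx(200 / 3)
        assert simil == 100.0  # D-E scores +2

    def test_nonconservative_change(self):
        ident, simil = pair_identity_similarity("AAAA", "AAAW")
        assert ident == 75.0 and simil == 75.0  # A-W scores -3

    def test_position_subset(self):
        ident, simil = pair_identity_similarity("AW", "AA", positions=[0])
        assert ident == 100.0 and simil == 100.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pair_identity_similarity("AA", "AAA")

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        pep=st.lists(
            st.tuples(st.sampled_from(AMINO_ACIDS), st.sampled_from(AMINO_ACIDS)),
            min_size=1, max_size=40,
        )
    )
    def test_identity_bounded_by_similarity_and_symmetric(self, pep):
        a = "".join(x for x, _ in pep)
        b = "".join(y for _, y in pep)
        ident, simil = pair_identity_similarity(a, b)
        assert 0 <= ident <= simil <= 100
        assert pair_identity_similarity(b, a) == (ident, simil)


def two_allele_set():
    # peptides: a -> "FA" (TTT GCT), b -> "FW" (TTT TGG): identity 50
    return AlleleSequenceSet({"a": "TTTGCT", "b": "TTTTGG"})


class TestPopulationSimilarity:
    def test_single_homozygote(self):
        seqs = two_allele_set()
        g = make_table([("a", "a")])
        s = population_similarity(g, seqs, "p1")
        assert s.identity_mean == 100.0 and s.identity_sd == 0.0

    def test_copies_mode_includes_within_individual_pairs(self):
        seqs = two_allele_set()
        g = make_table([("a", "a"), ("b", "b")])
        s = population_similarity(g, seqs, "p1", mode="copies")
        # 6 copy pairs: 2 identical (100) + 4 cross pairs at 50
        assert s.identity_mean == pytest.approx((2 * 100 + 4 * 50) / 6)

    def test_unique_mode_scores_distinct_alleles_once(self):
        seqs = two_allele_set()
        g = make_table([("a", "a"), ("b", "b"), ("a", "b")])
        s = population_similarity(g, seqs, "p1", mode="unique")
        assert s.identity_mean == pytest.approx(50.0)

    def test_identity_never_exceeds_similarity(self, pool):
        cfg = SimulationConfig(seed=31, n_individuals=40)
        g = simulate_metapopulation(cfg, pool)
        for region in ("beta1", "pbr"):
            s = population_similarity(
                g, pool, "pop1", region=region, mask=cfg.pbr_mask
            )
            assert s.identity_mean <= s.similarity_mean

    def test_missing_sequence_named(self):
        seqs = two_allele_set()
        g = make_table([("a", "zz")])
        with pytest.raises(ValidationError, match="zz"):
            population_similarity(g, seqs, "p1")


class TestPBRProfile:
    def test_single_allele_rows_are_indicators(self):
        seqs = two_allele_set()
        g = make_table([("a", "a")])
        mask = PBRMask((1, 2))
        prof = pbr_profile(g, seqs, "p1", mask)
        assert np.allclose(prof.matrix.sum(axis=1), 1.0)
        assert set(np.unique(prof.matrix)) == {0.0, 1.0}

    def test_two_alleles_split_frequency_at_variable_position(self):
        seqs = two_allele_set()
        g = make_table([("a", "b")])
        mask = PBRMask((1, 2))
        prof = pbr_profile(g, seqs, "p1", mask)
        col_a = AMINO_ACIDS.index("A")
        col_w = AMINO_ACIDS.index("W")
        assert prof.matrix[1, col_a] == pytest.approx(0.5)
        assert prof.matrix[1, col_w] == pytest.approx(0.5)
        assert prof.matrix[0, AMINO_ACIDS.index("F")] == pytest.approx(1.0)

    def test_full_pbr_vector_has_620_coordinates(self, pool):
        mask31 = PBRMask(tuple(range(9, 40)))  # any 31 positions
        cfg = SimulationConfig(seed=33, n_individuals=20)
        g = simulate_metapopulation(cfg, pool)
        prof = pbr_profile(g, pool, "pop1", mask31)
        assert prof.vector.shape == (620,)

    def test_frequency_weighting_changes_rows(self, pool):
        cfg = SimulationConfig(seed=35, n_individuals=40)
        g = simulate_metapopulation(cfg, pool)
        p_u = pbr_profile(g, pool, "pop1", cfg.pbr_mask)
        p_w = pbr_profile(g, pool, "pop1", cfg.pbr_mask, weighting="frequency_weighted")
        assert not np.allclose(p_u.matrix, p_w.matrix)


def indicator_profile(pop, mask, residues):
    m = np.zeros((len(mask), len(AMINO_ACIDS)))
    for i, r in enumerate(residues):
        m[i, AMINO_ACIDS.index(r)] = 1.0
    return PBRProfile(pop, mask, m, "allele_unweighted")


class TestProfileCorrelation:
    def test_identical_profiles_fully_correlated(self):
        mask = PBRMask((1, 2, 3))
        profs = [indicator_profile(p, mask, "ACD") for p in ("x", "y", "z")]
        matrix, global_pcc = profile_correlation(profs)
        assert np.allclose(matrix.values, 1.0)
        assert global_pcc == pytest.approx(1.0)

    def test_disjoint_residue_usage_anticorrelated(self):
        mask = PBRMask((1, 2))
        pa = indicator_profile("a", mask, "AC")
        pb = indicator_profile("b", mask, "DE")
        matrix, _ = profile_correlation([pa, pb])
        assert matrix.get("a", "b") < 0

    def test_pocket_restriction_equals_subvector_correlation(self, pool):
        cfg = SimulationConfig(seed=37, n_individuals=30, n_populations=2)
        g = simulate_metapopulation(cfg, pool)
        profs = [pbr_profile(g, pool, p, cfg.pbr_mask) for p in g.populations()]
        matrix, _ = profile_correlation(profs, pocket="P4")
        va = profs[0].pocket_vector("P4")
        vb = profs[1].pocket_vector("P4")
        assert matrix.get("pop1", "pop2") == pytest.approx(
            float(np.corrcoef(va, vb)[0, 1])
        )

    def test_population_order_invariance(self, pool):
        cfg = SimulationConfig(seed=39, n_individuals=30, n_populations=3)
        g = simulate_metapopulation(cfg, pool)
        profs = [pbr_profile(g, pool, p, cfg.pbr_mask) for p in g.populations()]
        _, g1 = profile_correlation(profs)
        _, g2 = profile_correlation(profs[::-1])
        assert g1 == pytest.approx(g2)

    def test_mismatched_masks_rejected(self):
        pa = indicator_profile("a", PBRMask((1, 2)), "AC")
        pb = indicator_profile("b", PBRMask((1, 3)), "AC")
        with pytest.raises(ValidationError):
            profile_correlation([pa, pb])


class TestUpgma:
    def test_hand_example(self):
        m = PairwiseMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]]),
            "da",
        )
        assert upgma(m) == "((A:0.1,B:0.1):0.2,C:0.3);"

    def test_two_leaves_split_distance(self):
        m = PairwiseMatrix(["x", "y"], np.array([[0, 0.5], [0.5, 0]]), "da")
        assert upgma(m) == "(x:0.25,y:0.25);"

    def test_ultrametric_output(self):
        rng = np.random.default_rng(2)
        labels = [f"L{i}" for i in range(6)]
        d = rng.uniform(0.1, 1.0, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        newick = upgma(PairwiseMatrix(labels, d, "da"))
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_row_order_invariance(self):
        labels = ["b", "d", "a", "c"]
        rng = np.random.default_rng(3)
        d = rng.uniform(0.1, 1.0, size=(4, 4))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        m1 = PairwiseMatrix(labels, d, "da")
        perm = [2, 0, 3, 1]
        m2 = PairwiseMatrix(
            [labels[i] for i in perm], d[np.ix_(perm, perm)], "da"
        )
        assert upgma(m1) == upgma(m2)

    def test_correlation_matrix_transformed(self):
        m = PairwiseMatrix(
            ["a", "b"], np.array([[1.0, 0.9], [0.9, 1.0]]), "pcc"
        )
        assert upgma(m) == "(a:0.05,b:0.05);"
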