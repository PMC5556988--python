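"""Majority consensus, K2P distances, and the neighbor-joining utility."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tepaleo as tp
from tepaleo.consensus import (
    DistanceMatrix,
    SaturationError,
    consensus_matrix,
    p_distance,
)
from tepaleo.simulate import random_sequence

DNA = st.text(alphabet="ACGT", min_size=10, max_size=60)


class TestK2P:
    def test_identical_sequences_give_zero(self):
        assert tp.k2p_distance("ACGTACGTAC", "ACGTACGTAC") == 0.0

    def test_hand_computed_case(self):
        # 10 sites, 1 transition (A->G), 1 transversion (A->C):
        # d = -1/2 ln((1-2*.1-.1) sqrt(1-2*.1)) = 0.234123...
        a = "AAAAAAAAAA"
        b = "GCAAAAAAAA"
        expected = -0.5 * math.log(0.7 * math.sqrt(0.8))
        assert tp.k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert tp.k2p_distance(a, b) == pytest.approx(0.2341, abs=1e-4)

    def test_gapped_and_ambiguous_sites_are_pairwise_deleted(self):
        a = "A-GTANGTAC"
        b = "ACGTACGTA-"
        # usable sites exclude columns 1 (gap), 5 (N), 9 (gap)
        assert tp.k2p_distance(a, b) == 0.0

    def test_no_usable_sites_raises(self):
        with pytest.raises(ValueError):
            tp.k2p_distance("----", "ACGT")

    def test_saturation_is_signalled(self):
        a = "A" * 40
        b = "G" * 40  # all transitions: P=1 -> log argument <= 0
        with pytest.raises(SaturationError):
            tp.k2p_distance(a, b)

    @given(a=DNA, b=DNA)
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_p_distance_bound(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        try:
            d_ab = tp.k2p_distance(a, b)
            d_ba = tp.k2p_distance(b, a)
        except SaturationError:
            return
        assert d_ab == pytest.approx(d_ba)
        assert d_ab >= p_distance(a, b) - 1e-12
        assert (d_ab == 0) == (a == b)


class TestMajorityConsensus:
    def test_identical_copies_return_the_copy(self, rng):
        ref = random_sequence(200, 0.5, rng)
        prof = tp.build_majority_consensus([ref] * 5, ref)
        assert prof.sequence == ref
        assert prof.n_copies == 5

    def test_majority_rule_per_column(self):
        ref = "AAAATTTTGGGG"
        copies = [ref, ref, ref[:4] + "C" + ref[5:]]
        prof = tp.build_majority_consensus(copies, ref)
        assert prof.sequence == ref  # A,A,C column -> A... T majority kept

    def test_simulated_family_recovers_ancestor(self, rng):
        anc = random_sequence(800, 0.5, rng)
        copies = [tp.evolve_sequence(anc, 0.05, seed=rng) for _ in range(20)]
        prof = tp.build_majority_consensus(copies, anc)
        ident = sum(x == y for x, y in zip(prof.sequence, anc)) / len(anc)
        assert ident >= 0.99

    def test_consensus_is_idempotent(self, rng):
        ref = random_sequence(300, 0.5, rng)
        prof = tp.build_majority_consensus([ref], ref)
        again = tp.build_majority_consensus([prof.sequence], prof.sequence)
        assert again.sequence == prof.sequence

    def test_low_coverage_columns_dropped(self, rng):
        # MITE-like family: internal region has no coverage
        ref = random_sequence(600, 0.5, rng)
        mites = [ref[:150] + ref[450:] for _ in range(5)]
        prof = tp.build_majority_consensus(mites, ref, min_coverage=0.2)
        assert len(prof.sequence) == 300

    def test_consensus_closer_to_ancestor_than_copies(self, rng):
        anc = random_sequence(1000, 0.5, rng)
        copies = [tp.evolve_sequence(anc, 0.1, seed=rng) for _ in range(20)]
        prof = tp.build_majority_consensus(copies, anc)
        d_cons = tp.k2p_distance(prof.sequence, anc)
        d_copies = np.mean([tp.k2p_distance(c, anc) for c in copies])
        assert d_cons < d_copies

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            tp.build_majority_consensus([], "ACGT")


class TestDivergenceTable:
    def test_one_record_per_copy_and_zero_for_identical(self, rng):
        ref = random_sequence(400, 0.5, rng)
        copies = [ref, ref, tp.evolve_sequence(ref, 0.05, seed=rng)]
        prof = tp.build_majority_consensus(copies, ref)
        recs = tp.divergence_table(copies, prof)
        assert len(recs) == 3
        assert recs[0].k2p == pytest.approx(0.0, abs=1e-9)

    def test_burst_mean_matches_dating_expectation(self, rng):
        anc = random_sequence(1300, 0.5, rng)
        copies = [
            tp.evolve_sequence(anc, 2 * 1.9e-3 * 10, seed=rng) for _ in range(50)
        ]
        prof = tp.build_majority_consensus(copies, anc)
        recs = tp.divergence_table(copies, prof)
        ks = [r.k2p for r in recs if not r.saturated]
        assert len(ks) == 50
        assert np.mean(ks) == pytest.approx(0.038, abs=0.006)


class TestDistanceMatrixAndNJ:
    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[1, 1], [1, 0]]))

    def test_consensus_matrix_is_symmetric_zero_diagonal(self, rng):
        anc = random_sequence(500, 0.5, rng)
        profs = []
        for sp in ("s1", "s2", "s3"):
            seqs = [tp.evolve_sequence(anc, 0.05, seed=rng) for _ in range(3)]
            profs.append(tp.build_majority_consensus(seqs, anc, sp))
        dm = consensus_matrix(profs)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_three_taxon_branch_lengths_solve_three_point_formulas(self):
        # path lengths in the NJ tree must equal the input distances
        import dendropy

        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        tree = dendropy.Tree.get(data=tp.nj_tree(dm), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(0.3, abs=1e-6)
        assert pdm.distance(taxa["a"], taxa["c"]) == pytest.approx(0.5, abs=1e-6)
        assert pdm.distance(taxa["b"], taxa["c"]) == pytest.approx(0.6, abs=1e-6)

    def test_additive_four_taxon_topology_recovered(self):
        # tree ((a,b),(c,d)) with internal branch 0.2
        labels = ["a", "b", "c", "d"]
        m = np.array(
            [
                [0.0, 0.3, 0.9, 1.0],
                [0.3, 0.0, 1.0, 1.1],
                [0.9, 1.0, 0.0, 0.5],
                [1.0, 1.1, 0.5, 0.0],
            ]
        )
        newick = tp.nj_tree(DistanceMatrix(labels, m))
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.encode_bipartitions()
        splits = {
            frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            for node in tree if not node.is_leaf()
        }
        assert {"a", "b"} in splits or {"c", "d"} in splits

    def test_agrees_with_dendropy_nj_on_random_additive_matrix(self, rng):
        import dendropy

        # build an additive matrix from a random tree's path lengths
        taxa = ["t1", "t2", "t3", "t4", "t5"]
        src = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0,
            taxon_namespace=dendropy.TaxonNamespace(taxa),
            num_extant_tips=5, rng=__import__("random").Random(1),
        )
        pdm = src.phylogenetic_distance_matrix()
        ns = src.taxon_namespace
        m = np.array(
            [[pdm.distance(ns[i], ns[j]) for j in range(5)] for i in range(5)]
        )
        ours = dendropy.Tree.get(
            data=tp.nj_tree(DistanceMatrix(list(t.label for t in ns), m)),
            schema="newick", taxon_namespace=ns,
        )
        theirs = pdm.nj_tree()
        ours.encode_bipartitions()
        theirs.encode_bipartitions()
        d = dendropy.calculate.treecompare.symmetric_difference(ours, theirs)
        assert d == 0

    def test_equal_distances_resolve_deterministically(self):
        m = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(["a", "b", "c", "d"], m)
        assert tp.nj_tree(dm) == tp.nj_tree(dm)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            tp.nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))
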