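import itertools

import dendropy
import numpy as np
import pytest

import motuforge as mf
from motuforge.distances import DistanceMatrix
from motuforge.errors import ValidationError
from motuforge.simulate import SimConfig, simulate_reference_library
from motuforge.trees import collapse_haplotypes, is_ultrametric, nj_tree, upgma_tree


def path_lengths(tree):
    """Leaf-to-leaf path lengths keyed by frozenset of labels."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    return {
        frozenset((a.label, b.label)): pdm.distance(a, b)
        for a, b in itertools.combinations(taxa, 2)
    }


class TestNJ:
    def test_three_taxa_solves_three_point_system(self):
        d = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        pl = path_lengths(tree)
        assert pl[frozenset(("a", "b"))] == pytest.approx(0.2, abs=1e-9)
        assert pl[frozenset(("a", "c"))] == pytest.approx(0.3, abs=1e-9)
        assert pl[frozenset(("b", "c"))] == pytest.approx(0.4, abs=1e-9)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # additive matrix from a known tree: ((a:1,b:2):3,(c:4,d:5))
        ids = ["a", "b", "c", "d"]
        d = np.array([
            [0, 3, 8, 9],
            [3, 0, 9, 10],
            [8, 9, 0, 9],
            [9, 10, 9, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(ids, d))
        pl = path_lengths(tree)
        for i, j in itertools.combinations(range(4), 2):
            assert pl[frozenset((ids[i], ids[j]))] == pytest.approx(d[i, j], abs=1e-9)
        # correct unrooted topology: a-b vs c-d split
        bip = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
               for e in tree.preorder_edge_iter() if e.head_node.is_internal()}
        assert any(s in ({"a", "b"}, {"c", "d"}) for s in map(set, bip))

    def test_fewer_than_three_ids_errors(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(["a", "b"], d))

    def test_recovers_species_topology_from_simulated_matrices(self):
        # low-divergence simulated libraries, one sequence per species: the
        # estimate contains every resolved split of the generating species
        # tree (splits on near-zero branches are ties, hence collapsed) in
        # >= 95/100 replicates
        hits = 0
        for seed in range(100):
            cfg = SimConfig(n_species=8, seqs_min=1, seqs_max=1, seqs_mean=1,
                            seed=seed + 300, crown_depth=0.08, stem_scale=0.02)
            lib, truth = simulate_reference_library(cfg)
            dm = mf.pairwise_matrix(lib)
            est = nj_tree(dm)
            for leaf in est.leaf_node_iter():
                leaf.taxon.label = truth.nominal[leaf.taxon.label]
            tns = dendropy.TaxonNamespace()
            est2 = dendropy.Tree.get(data=est.as_string(schema="newick"),
                                     schema="newick", taxon_namespace=tns)
            true2 = dendropy.Tree.get(data=truth.species_tree.as_string(schema="newick"),
                                      schema="newick", taxon_namespace=tns)
            # splits carried by very short true branches (< 5 expected
            # substitutions over the alignment) routinely realise zero
            # mutations and are unidentifiable from the data: collapse
            # them in the reference before comparing
            resolvable = 5.0 / cfg.seq_length
            for t in (est2, true2):
                t.is_rooted = False
            for e in true2.preorder_edge_iter():
                if (e.length is not None and e.length < resolvable
                        and e.head_node.is_internal()):
                    e.collapse()
            est2.encode_bipartitions()
            true2.encode_bipartitions()
            _fp, fn = dendropy.calculate.treecompare.false_positives_and_negatives(
                true2, est2)
            hits += fn == 0
        assert hits >= 95


class TestUPGMA:
    def test_output_is_ultrametric(self, toy_library):
        dm = mf.pairwise_matrix(toy_library)
        tree = upgma_tree(dm)
        ok, _worst, _spread = is_ultrametric(tree, tol=1e-9)
        assert ok

    def test_exact_reconstruction_of_ultrametric_matrix(self):
        # matrix generated from a clock tree: heights 1 (a,b), 2 ((ab),c)
        ids = ["a", "b", "c"]
        d = np.array([[0, 2.0, 4.0], [2.0, 0, 4.0], [4.0, 4.0, 0]])
        tree = upgma_tree(DistanceMatrix(ids, d))
        pl = path_lengths(tree)
        assert pl[frozenset(("a", "b"))] == pytest.approx(2.0)
        assert pl[frozenset(("a", "c"))] == pytest.approx(4.0)

    def test_matches_hand_agglomeration_on_toy_4x4(self):
        # merge a,b at 2 -> height 1; merge c,d at 4 -> height 2; final
        # merge at mean cross distance 8 -> height 4
        ids = ["a", "b", "c", "d"]
        d = np.array([
            [0, 2, 8, 8],
            [2, 0, 8, 8],
            [8, 8, 0, 4],
            [8, 8, 4, 0],
        ], dtype=float)
        tree = upgma_tree(DistanceMatrix(ids, d))
        pl = path_lengths(tree)
        assert pl[frozenset(("a", "b"))] == pytest.approx(2.0)
        assert pl[frozenset(("c", "d"))] == pytest.approx(4.0)
        assert pl[frozenset(("a", "c"))] == pytest.approx(8.0)

    def test_heights_monotone_root_to_leaf(self, easy_sim):
        lib, _ = easy_sim
        dm = mf.pairwise_matrix(lib)
        tree = upgma_tree(dm)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length >= 0


class TestCollapseHaplotypes:
    def test_identical_sequences_merge(self):
        lib = mf.ReferenceLibrary([
            mf.SequenceRecord("x", "ACGT"), mf.SequenceRecord("y", "ACGT"),
        ])
        reduced, members = collapse_haplotypes(lib)
        assert len(reduced) == 1 and members == {"x": ["x", "y"]}

    def test_all_distinct_is_identity(self, toy_library):
        reduced, members = collapse_haplotypes(toy_library)
        assert len(reduced) == len(toy_library)
        assert all(v == [k] for k, v in members.items())

    def test_n_site_difference_merges(self):
        lib = mf.ReferenceLibrary([
            mf.SequenceRecord("x", "ACGT"), mf.SequenceRecord("y", "ACNT"),
        ])
        reduced, members = collapse_haplotypes(lib)
        assert len(reduced) == 1 and members["x"] == ["x", "y"]
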