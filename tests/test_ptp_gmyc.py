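import math

import dendropy
import numpy as np
import pytest

import motuforge as mf
from motuforge.delimitation import gmyc_fit, ptp_fit
from motuforge.delimitation.gmyc import _UTree, _fit
from motuforge.errors import ValidationError
from motuforge.partition import Partition
from motuforge.simulate import SimConfig, simulate_reference_library
from motuforge.trees import collapse_haplotypes, midpoint_root, nj_tree, upgma_tree


def two_species_tree():
    """Two tight 4-leaf clusters separated by long stems."""
    nwk = ("((a1:0.002,(a2:0.001,a3:0.001):0.001):0.05,"
           "(b1:0.002,(b2:0.001,b3:0.001):0.001):0.05);")
    return dendropy.Tree.get(data=nwk, schema="newick")


def exponential_tree(n_leaves: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random topology with iid exponential branch lengths (one rate)."""
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_leaves)])
    tree = dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=taxa,
        pop_size=1,
        rng=__import__("random").Random(int(rng.integers(2**31))),
    )
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.exponential(0.01))
    return tree


class TestPTP:
    def test_two_rate_classes_recovered(self):
        part, model = ptp_fit(two_species_tree(), mode="single", seed=0)
        assert model.significant
        groups = {frozenset(v) for v in part.groups().values()}
        assert groups == {frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2", "b3"})}
        assert model.lambda_sp < model.lambda_coal

    def test_zero_length_cherry_stays_together(self):
        nwk = ("((a1:0.0,a2:0.0):0.03,((b1:0.002,b2:0.003):0.001,b3:0.004):0.05);")
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        part, _model = ptp_fit(tree, seed=0)
        assert part.assignment["a1"] == part.assignment["a2"]

    def test_star_tree_warns_and_returns_one_motu(self):
        nwk = "(a:0.1,b:0.1,c:0.1,d:0.1);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        with pytest.warns(UserWarning):
            part, model = ptp_fit(tree, seed=0)
        assert part.k == 1 and not model.significant

    def test_single_exponential_trees_prefer_null(self):
        # all branch lengths from one exponential: the one-species null
        # should be preferred in >= 90 of 100 replicates
        rng = np.random.default_rng(42)
        kept = 0
        for _ in range(100):
            tree = exponential_tree(12, rng)
            _part, model = ptp_fit(tree, mode="single", n_restarts=4, seed=1)
            kept += not model.significant
        assert kept >= 90

    def test_strong_rate_contrast_recovers_truth(self):
        # simulated genealogies with deep stems: median ARI >= 0.9
        aris = []
        for seed in range(10):
            cfg = SimConfig(n_species=10, seed=seed + 50)
            lib, truth = simulate_reference_library(cfg)
            dm = mf.pairwise_matrix(lib)
            haplo, members = collapse_haplotypes(lib)
            tree = midpoint_root(nj_tree(dm.submatrix(haplo.ids)))
            part, _model = ptp_fit(tree, seed=seed)
            aris.append(part.expand(members).ari(Partition("T", truth.molecular)))
        assert np.median(aris) >= 0.9

    def test_total_partition_and_mode_validation(self):
        tree = two_species_tree()
        part, _ = ptp_fit(tree, seed=0)
        assert part.ids == {"a1", "a2", "a3", "b1", "b2", "b3"}
        with pytest.raises(ValidationError):
            ptp_fit(tree, mode="bogus")


class TestGMYC:
    def test_two_leaf_tree_degenerate(self):
        tree = dendropy.Tree.get(data="(a:1,b:1);", schema="newick")
        with pytest.warns(UserWarning):
            part, model = gmyc_fit(tree)
        assert part.k == 1 and model.thresholds == []

    def test_non_ultrametric_error_names_worst_leaf(self):
        tree = dendropy.Tree.get(data="((a:1,b:5):1,(c:1,d:1):1);", schema="newick")
        with pytest.raises(ValidationError, match="b"):
            gmyc_fit(tree)

    def test_polytomy_rejected(self):
        tree = dendropy.Tree.get(data="((a:1,b:1,c:1):1,d:2);", schema="newick")
        with pytest.raises(ValidationError, match="binary"):
            gmyc_fit(tree)

    def test_clear_threshold_recovered(self):
        # true ultrametric genealogy with deep species stems: the fitted
        # clusters should reproduce the species membership exactly
        cfg = SimConfig(n_species=8, seqs_min=4, seqs_max=4, seqs_mean=4, seed=9)
        _lib, truth = simulate_reference_library(cfg)
        part, model = gmyc_fit(truth.genealogy, seed=0)
        assert model.significant
        truth_groups = {}
        for sid, sp in truth.molecular.items():
            truth_groups.setdefault(sp, set()).add(sid)
        groups = {frozenset(v) for v in part.groups().values()}
        assert groups == {frozenset(v) for v in truth_groups.values()}

    def test_chosen_threshold_maximises_scanned_likelihood(self, easy_sim):
        lib, _ = easy_sim
        dm = mf.pairwise_matrix(lib)
        haplo, _ = collapse_haplotypes(lib)
        sub = dm.submatrix(haplo.ids[:40])      # <= 50 leaves, exhaustive scan
        tree = upgma_tree(sub)
        _part, model = gmyc_fit(tree, seed=0)
        best_in_scan = max(l for _t, l in model.notes["scan"])
        assert model.logL >= best_in_scan - 1e-6
        assert len(model.notes["scan"]) == 39    # one candidate per internal node

    def test_loglik_matches_independent_interval_computation(self):
        """The pooled-rate likelihood equals a naive re-derivation that
        walks the tree intervals directly."""
        nwk = ("((a1:0.004,a2:0.004):0.096,((b1:0.003,b2:0.003):0.002,"
               "b3:0.005):0.095);")
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        rng = np.random.default_rng(0)
        ut = _UTree(tree, tol=1e-6, rng=rng)
        m = ut.m
        for j in range(1, m + 1):
            spec = np.zeros(m, dtype=bool)
            spec[:j] = True
            logL, params, _ = _fit(ut, spec)
            lam1, p1 = params["lambda_yule"], params["p_yule"]
            lam2, p2 = params["lambda_coal"], params["p_coal"]
            # naive: iterate intervals between sorted ages; count species
            # lineages and per-cluster lineages crossing each interval
            ages = list(ut.age) + [0.0]
            clusters = ut.clusters(spec)
            naive = 0.0
            for i in range(m):
                dt = ages[i] - ages[i + 1]
                n_sp = 1 + int(spec[: i + 1].sum())
                b = 0.0
                if lam1 is not None:
                    b += lam1 * (n_sp ** p1 - 1.0)
                if lam2 is not None:
                    for members in clusters:
                        n_k = 1 + sum(1 for r in sorted(members) if r <= i)
                        b += lam2 * n_k * (n_k - 1.0) ** p2
                naive -= b * dt
                if i < m - 1:
                    naive += math.log(b)
            assert naive == pytest.approx(logL, abs=1e-8)

    def test_null_coalescent_rarely_rejected(self):
        rejections = 0
        for seed in range(30):
            cfg = SimConfig(n_species=1, seqs_min=15, seqs_max=15, seqs_mean=15,
                            seed=seed + 700)
            lib, _ = simulate_reference_library(cfg)
            dm = mf.pairwise_matrix(lib)
            haplo, _ = collapse_haplotypes(lib)
            sub = dm.submatrix(haplo.ids)
            if sub.n < 3:
                continue
            _part, model = gmyc_fit(upgma_tree(sub), seed=seed)
            rejections += model.significant
        assert rejections <= 3

    def test_multiple_mode_runs_and_keeps_partition_total(self, easy_sim):
        lib, _truth = easy_sim
        dm = mf.pairwise_matrix(lib)
        haplo, members = collapse_haplotypes(lib)
        tree = upgma_tree(dm.submatrix(haplo.ids))
        part, model = gmyc_fit(tree, mode="multiple", seed=0)
        assert part.expand(members).ids == frozenset(lib.ids)
        assert model.mode == "multiple" and len(model.thresholds) >= 1
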