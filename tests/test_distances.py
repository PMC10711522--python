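import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import motuforge as mf
from motuforge.distances import (
    PairwiseCounts,
    count_site_patterns,
    k2p_distance,
    pairwise_matrix,
    rank_summaries,
    species_gap_records,
)
from motuforge.errors import SingleSpeciesError, UndefinedComparisonError
from motuforge.simulate import SimConfig, simulate_reference_library

from conftest import brute_force_k2p, random_dna


class TestSitePatterns:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", (0, 0, 4)),
            ("ACGT", "GCGT", (1, 0, 4)),   # A<->G transition
            ("ACG-", "ACGT", (0, 0, 3)),   # gap site dropped
            ("ACGT", "AAGT", (0, 1, 4)),   # C->A transversion
            ("NCGT", "ACGT", (0, 0, 3)),   # N treated as missing
            ("RCGT", "ACGT", (0, 0, 3)),   # ambiguity treated as missing
        ],
    )
    def test_examples(self, a, b, expected):
        c = count_site_patterns(a, b)
        assert (c.ts, c.tv, c.m) == expected

    def test_no_resolved_sites(self):
        with pytest.raises(UndefinedComparisonError):
            count_site_patterns("NNNN", "ACGT")

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(rng, 120, "ACGTN-")
        b = random_dna(rng, 120, "ACGTN-")
        try:
            mine = k2p_distance(count_site_patterns(a, b))
        except UndefinedComparisonError:
            assert brute_force_k2p(a, b) is None
            return
        oracle = brute_force_k2p(a, b)
        if math.isnan(oracle):
            assert math.isnan(mine)
        else:
            assert mine == pytest.approx(oracle, abs=1e-12)


class TestK2PDistance:
    def test_identical_sequences(self):
        assert k2p_distance(PairwiseCounts(0, 0, 600)) == 0.0

    def test_closed_form_hand_value(self):
        # P = Q = 0.1 -> -0.5*ln(0.7*sqrt(0.8)) ~ 0.2341
        d = k2p_distance(PairwiseCounts(1, 1, 10))
        assert d == pytest.approx(-0.5 * math.log(0.7 * math.sqrt(0.8)), abs=1e-12)
        assert round(d, 4) == 0.2341

    def test_saturation_flagged(self):
        assert math.isnan(k2p_distance(PairwiseCounts(5, 0, 10)))  # P=0.5, Q=0

    def test_estimator_unbiased_under_k80(self):
        # simulated pairs at true divergence delta: estimator mean within
        # 3 standard errors over 500 replicates
        from motuforge.simulate import evolve_k80

        rng = np.random.default_rng(11)
        delta, length = 0.08, 652
        estimates = []
        for _ in range(500):
            anc = rng.integers(0, 4, size=length, dtype=np.uint8)
            a = evolve_k80(anc, delta / 2, 8.0, rng)
            b = evolve_k80(anc, delta / 2, 8.0, rng)
            bases = "ACGT"
            sa = "".join(bases[x] for x in a)
            sb = "".join(bases[x] for x in b)
            estimates.append(k2p_distance(count_site_patterns(sa, sb)))
        mean = float(np.mean(estimates))
        se = float(np.std(estimates, ddof=1)) / math.sqrt(len(estimates))
        assert abs(mean - delta) < 3 * se


class TestPairwiseMatrix:
    def test_single_sequence(self):
        lib = mf.ReferenceLibrary([mf.SequenceRecord("x", "ACGT")])
        dm = pairwise_matrix(lib)
        assert dm.d.shape == (1, 1) and dm.d[0, 0] == 0.0

    def test_symmetry_and_zero_diagonal(self, toy_library):
        dm = pairwise_matrix(toy_library)
        assert np.allclose(dm.d, dm.d.T, equal_nan=True)
        assert np.all(np.diag(dm.d) == 0.0)

    def test_equals_per_pair_oracle_on_simulated_library(self):
        cfg = SimConfig(n_species=3, seqs_min=1, seqs_max=3, seqs_mean=2,
                        seq_length=200, seed=5)
        lib, _ = simulate_reference_library(cfg)
        dm = pairwise_matrix(lib)
        for i in range(len(lib)):
            for j in range(i + 1, len(lib)):
                oracle = brute_force_k2p(lib.records[i].seq, lib.records[j].seq)
                assert dm.d[i, j] == pytest.approx(oracle, abs=1e-12)


class TestGapRecords:
    def test_matches_exhaustive_scan_on_toy(self, toy_library):
        dm = pairwise_matrix(toy_library)
        records = {r.species: r for r in species_gap_records(dm, toy_library.species_of())}
        species = toy_library.species_of()
        ids = toy_library.ids
        for sp, rec in records.items():
            mine = [i for i, s in enumerate(ids) if species[s] == sp]
            other = [i for i, s in enumerate(ids) if species[s] != sp]
            intra = [dm.d[i, j] for i in mine for j in mine if i < j]
            hetero = [dm.d[i, j] for i in mine for j in other]
            assert rec.max_intra == pytest.approx(max(intra))
            assert rec.nn_dist == pytest.approx(min(hetero))

    def test_nn_is_mutual_pool_member(self, easy_sim):
        lib, _ = easy_sim
        dm = pairwise_matrix(lib)
        records = {r.species: r for r in species_gap_records(dm, lib.species_of())}
        for sp, rec in records.items():
            partner = records[rec.nn_taxon]
            # the distance attained by X's nearest neighbour appears in the
            # partner's heterospecific pool, so partner.nn <= rec.nn
            assert partner.nn_dist <= rec.nn_dist + 1e-12

    def test_single_species_errors(self):
        lib = mf.ReferenceLibrary([
            mf.SequenceRecord("x", "ACGT", species="sp"),
            mf.SequenceRecord("y", "ACGA", species="sp"),
        ])
        with pytest.raises(SingleSpeciesError):
            species_gap_records(pairwise_matrix(lib), lib.species_of())

    def test_singleton_species_has_undefined_max_intra(self, toy_library):
        lib = toy_library.subset(["a1", "b1", "b2"])
        dm = pairwise_matrix(lib)
        recs = {r.species: r for r in species_gap_records(dm, lib.species_of())}
        assert recs["alpha"].max_intra is None
        assert recs["alpha"].gap_present is None
        assert recs["beta"].gap_present is True


class TestRankSummaries:
    def test_exclusive_pools_are_disjoint_and_match_hand_pooling(self, toy_library):
        dm = pairwise_matrix(toy_library)
        out = rank_summaries(dm, toy_library.metadata_frame())
        # alpha/beta share genA; gamma in genB; all share famA
        sp = out["within_species"]
        gen = out["within_genus"]
        fam = out["within_family"]
        assert sp.n_pairs == 3          # one intra pair per species
        assert gen.n_pairs == 4         # alpha x beta pairs
        assert fam.n_pairs == 8         # {alpha,beta} x gamma pairs
        assert sp.n_groups == 3 and gen.n_groups == 2 and fam.n_groups == 1
        assert sp.min <= sp.mean <= sp.max
        assert gen.min > sp.max         # the toy gap

    def test_inclusive_pools_contain_lower_ranks(self, toy_library):
        dm = pairwise_matrix(toy_library)
        ex = rank_summaries(dm, toy_library.metadata_frame(), inclusive=False)
        inc = rank_summaries(dm, toy_library.metadata_frame(), inclusive=True)
        assert inc["within_genus"].n_pairs == ex["within_genus"].n_pairs + 3
        assert inc["within_genus"].min <= ex["within_genus"].min

    def test_single_genus_single_species_levels_absent(self):
        lib = mf.ReferenceLibrary([
            mf.SequenceRecord("x", "ACGT", "sp", "g", "f", "o"),
            mf.SequenceRecord("y", "ACGA", "sp", "g", "f", "o"),
        ])
        out = rank_summaries(pairwise_matrix(lib), lib.metadata_frame())
        assert out["within_species"] is not None
        assert out["within_genus"] is None
        assert out["within_family"] is None
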