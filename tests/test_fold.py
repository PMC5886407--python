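"""Folding engines: DP vs oracle, hotspots, hierarchical folding contracts."""

import pytest

from knotfold.energy import structure_energy
from knotfold.fixtures import (
    make_h_pseudoknot,
    make_hairpin,
    make_overcrowded_input,
    random_sequence,
)
from oracles import constrained_hfold_oracle

from knotfold.fold import (
    brute_force_fold,
    enumerate_stems,
    greedy_pk_fold,
    hierarchical_fold,
    hotspots,
    iterative_hfold,
    mfe_pkfree,
)
from knotfold.structures import (
    PairTable,
    RnaSequence,
    StructureError,
    is_pseudoknotted,
)


class TestMfePkfree:
    def test_poly_a_is_unfoldable(self, dp09):
        pred = mfe_pkfree(RnaSequence("pa", "A" * 10), dp09)
        assert pred.structure.pairs() == []
        assert pred.energy == 0.0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed, dp09):
        seq = random_sequence(11 + seed, seed=seed)
        dp = mfe_pkfree(seq, dp09)
        bf = brute_force_fold(seq, dp09, allow_pseudoknots=False)
        assert dp.energy == pytest.approx(bf.energy, abs=1e-9)

    def test_energy_field_is_self_consistent(self, dp09):
        seq = random_sequence(20, seed=77)
        pred = mfe_pkfree(seq, dp09)
        assert pred.energy == pytest.approx(
            structure_energy(seq, pred.structure, dp09), abs=1e-12
        )
        assert not is_pseudoknotted(pred.structure)

    def test_recovers_designed_hairpin(self, dp09):
        rec = make_hairpin(4, 4, seed=2)
        pred = mfe_pkfree(rec.sequence, dp09)
        assert pred.structure == rec.structure


class TestBruteForce:
    def test_min_hairpin_excludes_short_pair(self, dp09):
        pred = brute_force_fold(RnaSequence("x", "GAAC"), dp09)
        assert pred.structure.pairs() == []

    def test_refuses_long_sequences(self, dp09):
        with pytest.raises(ValueError, match="exceeds limit"):
            brute_force_fold(random_sequence(23, seed=0), dp09)
        with pytest.raises(ValueError, match="exceeds limit"):
            brute_force_fold(
                random_sequence(19, seed=0), dp09, allow_pseudoknots=True
            )

    def test_pseudoknotted_optimum_beats_pkfree_on_designed_fixture(self, dp09):
        rec = make_h_pseudoknot(3, 2, [2, 1, 3], seed=1)
        assert rec.sequence.n == 16
        pk = brute_force_fold(rec.sequence, dp09, allow_pseudoknots=True)
        free = brute_force_fold(rec.sequence, dp09, allow_pseudoknots=False)
        assert is_pseudoknotted(pk.structure)
        assert pk.energy < free.energy - 1e-9


class TestHotspots:
    def test_poly_a_has_no_stems(self, dp09):
        assert hotspots(RnaSequence("pa", "A" * 30), dp09) == []

    def test_unique_gc_stem_ranked_first(self, dp09):
        seq = RnaSequence("x", "GGGGGGAAAACCCCCC")
        hs = hotspots(seq, dp09)
        assert hs[0].pairs == tuple((i, 15 - i) for i in range(6))
        assert hs[0].energy == min(st.energy for st in enumerate_stems(seq, dp09))

    def test_never_more_than_twenty(self, dp09):
        seq = random_sequence(60, seed=3, gc_bias=0.8)
        assert len(hotspots(seq, dp09)) <= 20

    def test_sorted_ascending_and_maximal(self, dp09):
        seq = random_sequence(40, seed=9)
        hs = hotspots(seq, dp09)
        assert hs == sorted(hs, key=lambda s: (s.energy, len(s.pairs), s.pairs))
        assert all(len(st.pairs) >= 2 for st in hs)


class TestHierarchicalFold:
    def test_empty_input_reduces_to_mfe(self, dp09):
        seq = random_sequence(18, seed=5)
        hf = hierarchical_fold(seq, PairTable(seq.n), dp09)
        assert hf.structure == mfe_pkfree(seq, dp09).structure

    def test_rejects_pseudoknotted_input(self, dp09):
        rec = make_h_pseudoknot(2, 2, [2, 1, 3], seed=0)
        with pytest.raises(StructureError, match="pseudoknot-free"):
            hierarchical_fold(rec.sequence, rec.structure, dp09)

    def test_recovers_crossing_stem_from_stem1(self, dp09):
        rec = make_h_pseudoknot(3, 2, [2, 1, 3], seed=1)
        stem1 = PairTable.from_pairs(
            rec.sequence.n, [p for p in rec.structure.pairs() if p[0] < 3]
        )
        hf = hierarchical_fold(rec.sequence, stem1, dp09)
        assert set(stem1.pairs()) <= set(hf.structure.pairs())
        assert set(rec.structure.pairs()) <= set(hf.structure.pairs())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_constrained_oracle(self, seed, dp09):
        rec = make_h_pseudoknot(2, 2, [2, 1, 3], seed=seed)
        stem1 = PairTable.from_pairs(
            rec.sequence.n, [p for p in rec.structure.pairs() if p[0] < 2]
        )
        hf = hierarchical_fold(rec.sequence, stem1, dp09)
        assert hf.energy == pytest.approx(
            constrained_hfold_oracle(rec.sequence, stem1, dp09), abs=1e-9
        )

    def test_output_never_worse_than_input_alone(self, dp09):
        rec = make_hairpin(4, 4, seed=3)
        hf = hierarchical_fold(rec.sequence, rec.structure, dp09)
        assert hf.energy <= structure_energy(
            rec.sequence, rec.structure, dp09
        ) + 1e-9


class TestIterativeHfold:
    def test_monotone_chain_of_energies(self, dp09):
        for seed in range(4):
            rec = make_h_pseudoknot(2, 2, [2, 1, 3], seed=seed)
            stem1 = PairTable.from_pairs(
                rec.sequence.n, [p for p in rec.structure.pairs() if p[0] < 2]
            )
            e_input = structure_energy(rec.sequence, stem1, dp09)
            hf = hierarchical_fold(rec.sequence, stem1, dp09)
            ih = iterative_hfold(rec.sequence, inputs=[stem1], params=dp09)
            assert ih.energy <= hf.energy + 1e-9 <= e_input + 2e-9

    def test_drops_pairs_of_overcrowded_input(self, dp09):
        rec, G = make_overcrowded_input()
        hf = hierarchical_fold(rec.sequence, G, dp09)
        ih = iterative_hfold(rec.sequence, inputs=[G], params=dp09)
        assert set(G.pairs()) <= set(hf.structure.pairs())
        dropped = set(G.pairs()) - set(ih.structure.pairs())
        assert dropped
        assert ih.energy < hf.energy - 1e-9
        assert ih.structure == rec.structure  # recovers the designed pseudoknot

    def test_hotspot_inputs_on_hairpin_sequence_match_mfe(self, dp09):
        rec = make_hairpin(4, 4, seed=4)
        ih = iterative_hfold(rec.sequence, params=dp09)
        assert ih.energy == pytest.approx(
            mfe_pkfree(rec.sequence, dp09).energy, abs=1e-9
        )

    def test_empty_input_list_falls_back_to_unconstrained(self, dp09):
        seq = random_sequence(14, seed=8)
        ih = iterative_hfold(seq, inputs=[], params=dp09)
        assert ih.energy <= mfe_pkfree(seq, dp09).energy + 1e-9

    def test_skeleton_input_recovers_designed_pseudoknot(self, dp09):
        rec = make_h_pseudoknot(3, 2, [2, 1, 3], seed=1)
        stem1 = PairTable.from_pairs(
            rec.sequence.n, [p for p in rec.structure.pairs() if p[0] < 3]
        )
        ih = iterative_hfold(rec.sequence, inputs=[stem1], params=dp09)
        oracle = brute_force_fold(rec.sequence, dp09, allow_pseudoknots=True)
        assert ih.energy == pytest.approx(oracle.energy, abs=1e-9)


class TestGreedy:
    def test_poly_a_gives_single_empty_structure(self, dp09):
        preds = greedy_pk_fold(RnaSequence("pa", "A" * 25), dp09)
        assert len(preds) == 1
        assert preds[0].structure.pairs() == []

    def test_hairpin_sequence_first_output_is_the_stem(self, dp09):
        rec = make_hairpin(4, 4, seed=6)
        preds = greedy_pk_fold(rec.sequence, dp09)
        assert set(rec.structure.pairs()) <= set(preds[0].structure.pairs())

    def test_outputs_self_consistent_sorted_and_bounded(self, dp09):
        seq = random_sequence(36, seed=11, gc_bias=0.7)
        preds = greedy_pk_fold(seq, dp09)
        assert len(preds) <= 20
        energies = [p.energy for p in preds]
        assert energies == sorted(energies)
        for p in preds:
            assert p.energy == pytest.approx(
                structure_energy(seq, p.structure, dp09), abs=1e-12
            )
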