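"""Sequence-design algorithms: sweeps, greedy recoding, diversity, sizing."""

import math

import pytest

import codonhealth as ch
from codonhealth.recode import ConvergenceError, TargetRangeError


def translation(seq):
    return seq.protein


class TestMaxIndexRecode:
    def test_scores_one_and_enc_20(self, chi_weights, all_aa_parent):
        recoded = ch.max_index_recode(all_aa_parent, chi_weights)
        assert ch.geometric_index(recoded, chi_weights) == pytest.approx(1.0)
        assert ch.enc(ch.count_codons(recoded)) == pytest.approx(20.0)

    def test_argmax_per_family(self, code):
        w = ch.WeightTable(weights={"AAA": 1.0, "AAG": 0.3, "ATG": 1.0}, label="toy")
        cds = ch.max_index_recode("MK", w)
        assert cds.nucleotides == "ATGAAA"

    def test_prefix_returned_unmodified(self, chi_weights, all_aa_parent):
        low = ch.random_weight_table(seed=9)
        recoded = ch.max_index_recode(all_aa_parent, low)
        assert recoded.prefix_codons == all_aa_parent.prefix_codons
        assert translation(recoded) == translation(all_aa_parent)

    def test_tie_warns(self, code):
        w = ch.WeightTable(weights={"AAA": 1.0, "AAG": 1.0, "ATG": 1.0}, label="t")
        with pytest.warns(UserWarning, match="tied"):
            ch.max_index_recode("MK", w)


class TestSystematicRecodes:
    def test_41_recodes_from_full_alphabet_parent(self, all_aa_parent):
        out = ch.systematic_recodes(all_aa_parent)
        assert len(out) == 41

    def test_each_output_synonymous_and_single_swap(self, all_aa_parent, code):
        for old, new, seq in ch.systematic_recodes(all_aa_parent):
            assert translation(seq) == translation(all_aa_parent)
            assert seq.prefix_codons == all_aa_parent.prefix_codons
            diffs = {
                (a, b)
                for a, b in zip(all_aa_parent.codons, seq.codons)
                if a != b
            }
            assert diffs == {(old, new)}

    def test_count_formula(self, code, chi_weights):
        """Count = Σ (degeneracy − 1) over amino acids in the variable region."""
        protein = "MKLPR"
        parent = ch.max_index_recode(protein, chi_weights)
        out = ch.systematic_recodes(parent)
        expected = sum(code.degeneracy(aa) - 1 for aa in protein)
        assert len(out) == expected

    def test_met_trp_only_protein_yields_nothing(self, chi_weights):
        parent = ch.max_index_recode("MWMW", chi_weights)
        assert ch.systematic_recodes(parent) == []

    def test_ambiguous_parent_rejected(self, code):
        seq = ch.CodingSequence(id="x", nucleotides="ATGAAAAAG")  # AAA and AAG
        with pytest.raises(ValueError, match="single-codon"):
            ch.systematic_recodes(seq)


class TestAchievableRange:
    def test_met_only_protein(self, chi_weights):
        assert ch.achievable_range("MMM", chi_weights) == (1.0, 1.0)

    def test_closed_form_two_positions(self, code):
        w = ch.WeightTable(
            weights={"AAA": 1.0, "AAG": 0.25, "TGT": 1.0, "TGC": 0.04},
            label="toy",
        )
        lo, hi = ch.achievable_range("KC", w)
        assert lo == pytest.approx(math.sqrt(0.25 * 0.04))
        assert lo == pytest.approx(0.1)
        assert hi == pytest.approx(1.0)

    def test_floor_applies_to_zero_weights(self, code):
        w = ch.WeightTable(weights={"AAA": 1.0, "AAG": 0.0}, label="toy")
        lo, _ = ch.achievable_range("K", w)
        assert lo == pytest.approx(w.epsilon_floor)


class TestGreedyRecode:
    def test_reaches_target_and_re_scores(self, chi_weights):
        protein = ch.random_protein(200, seed=3)
        spec = ch.RecodeSpec(weights=chi_weights, target_index=0.75, seed=12)
        res = ch.greedy_recode(spec, protein)
        assert abs(res.achieved_index - 0.75) <= spec.tolerance
        # independent re-scoring of the emitted sequence
        rescored = ch.geometric_index(res.cds, chi_weights)
        assert rescored == pytest.approx(res.achieved_index, abs=1e-12)
        assert res.cds.protein == protein

    def test_deterministic_given_seed(self, chi_weights):
        protein = ch.random_protein(120, seed=4)
        spec = ch.RecodeSpec(weights=chi_weights, target_index=0.8, seed=99)
        a = ch.greedy_recode(spec, protein)
        b = ch.greedy_recode(spec, protein)
        assert a.cds.nucleotides == b.cds.nucleotides

    def test_target_above_range_errors(self, chi_weights):
        with pytest.raises(ValueError):
            ch.RecodeSpec(weights=chi_weights, target_index=1.01)
        spec = ch.RecodeSpec(weights=chi_weights, target_index=0.2, seed=0)
        lo, _ = ch.achievable_range("MKKK", chi_weights)
        if lo - spec.tolerance > 0.2:
            with pytest.raises(TargetRangeError):
                ch.greedy_recode(spec, "MKKK")

    def test_prefix_immutability_and_stop_preserved(self, chi_weights, all_aa_parent):
        with_stop = ch.CodingSequence(
            id="p", nucleotides=all_aa_parent.nucleotides + "TAA", fixed_prefix_len=17
        )
        spec = ch.RecodeSpec(
            weights=chi_weights, target_index=0.85, fixed_prefix_len=17, seed=5
        )
        res = ch.greedy_recode(spec, with_stop)
        assert res.cds.prefix_codons == with_stop.prefix_codons
        assert res.cds.codons[-1] == "TAA"
        assert res.cds.protein == with_stop.protein

    def test_non_convergence_carries_best(self, chi_weights):
        spec = ch.RecodeSpec(
            weights=chi_weights, target_index=0.75, tolerance=0.0001,
            seed=1, max_iterations=3,
        )
        with pytest.raises(ConvergenceError) as exc:
            ch.greedy_recode(spec, ch.random_protein(80, seed=2))
        assert exc.value.best is not None


class TestDiverseRecodeSet:
    def test_three_on_target_distinct_sequences(self, chi_weights):
        protein = ch.random_protein(150, seed=8)
        spec = ch.RecodeSpec(weights=chi_weights, target_index=0.85, seed=21)
        picked = ch.diverse_recode_set(
            spec, protein, k=3, candidates=12, min_dissimilarity=0.1
        )
        assert len(picked) == 3
        seqs = {r.cds.nucleotides for r in picked}
        assert len(seqs) == 3
        for r in picked:
            assert abs(r.achieved_index - 0.85) <= spec.tolerance
            assert r.cds.protein == protein

    def test_k_one_returns_closest(self, chi_weights):
        protein = ch.random_protein(100, seed=9)
        spec = ch.RecodeSpec(weights=chi_weights, target_index=0.9, seed=2)
        picked = ch.diverse_recode_set(spec, protein, k=1, candidates=5)
        assert len(picked) == 1

    def test_infeasible_dissimilarity_errors(self, chi_weights):
        protein = ch.random_protein(100, seed=10)
        spec = ch.RecodeSpec(weights=chi_weights, target_index=0.9, seed=3)
        with pytest.raises(ValueError, match="pairwise"):
            ch.diverse_recode_set(
                spec, protein, k=3, candidates=8, min_dissimilarity=1e6
            )

    def test_k_exceeding_pool_rejected(self, chi_weights):
        spec = ch.RecodeSpec(weights=chi_weights, target_index=0.9, seed=3)
        with pytest.raises(ValueError, match="candidate"):
            ch.diverse_recode_set(spec, "MKLV", k=5, candidates=3)


class TestMatchCUB:
    def test_self_match_reproduces_rscu(self, chi_weights):
        template = ch.random_cds(120, ch.random_weight_table(2), seed=6, id="tmpl")
        matched = ch.match_cub_recode(template, template.protein)
        a = ch.rscu(ch.count_codons(template))
        b = ch.rscu(ch.count_codons(matched))
        for codon, v in a.values.items():
            assert b.values[codon] == pytest.approx(v)
        assert matched.protein == template.protein

    def test_closer_than_unmatched_greedy(self, chi_weights, code):
        """CUB matching beats index-matched greedy recodes at RSCU distance."""
        import numpy as np

        from codonhealth.recode import _rscu_vector_59

        template = ch.random_cds(150, ch.random_weight_table(4), seed=7, id="tmpl")
        other = ch.random_protein(150, seed=77)
        matched = ch.match_cub_recode(template, other)
        tmpl_vec = _rscu_vector_59(ch.rscu(ch.count_codons(template)), code)

        def dist(seq):
            return float(
                np.linalg.norm(
                    _rscu_vector_59(ch.rscu(ch.count_codons(seq)), code) - tmpl_vec
                )
            )

        lo, hi = ch.achievable_range(other, chi_weights)
        target = ch.geometric_index(matched, chi_weights)
        target = min(max(target, lo + 0.02), hi - 0.01)
        wins = completed = 0
        for seed in range(10):
            spec = ch.RecodeSpec(
                weights=chi_weights, target_index=target, tolerance=0.01, seed=seed
            )
            try:
                greedy = ch.greedy_recode(spec, other)
            except ConvergenceError:
                continue
            completed += 1
            if dist(matched) <= dist(greedy.cds):
                wins += 1
        assert completed >= 5
        assert wins == completed

    def test_missing_family_falls_back_uniform(self, code):
        template = ch.CodingSequence(id="t", nucleotides="ATGAAAAAG")  # M, K only
        with pytest.warns(UserWarning, match="uniform"):
            matched = ch.match_cub_recode(template, "MKC")
        assert matched.protein == "MKC"


class TestSynonymousSpace:
    def test_no_choice_peptide(self):
        assert ch.synonymous_space_size("MW") == 1

    def test_degeneracy_product(self):
        assert ch.synonymous_space_size("KLR") == 2 * 6 * 6

    def test_fixed_prefix_excluded(self):
        assert ch.synonymous_space_size("KLR", fixed_prefix_len=1) == 6 * 6

    def test_scientific_notation_rounding(self):
        assert ch.scientific_notation(72) == "7.2e+1"
        assert ch.scientific_notation(1794 * 10**101) == "1.8e+104"
        assert ch.scientific_notation(995) == "1.0e+3"
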