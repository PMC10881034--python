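"""Codon counting, RSCU, relative adaptiveness, geometric indices and ENC."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import codonhealth as ch
from codonhealth.bias import ScoringError
from codonhealth.sequences import AlphabetError, FrameError


def make_counts(d):
    return ch.CodonCounts(counts=d, total=sum(d.values()))


class TestCountCodons:
    def test_direct_enumeration(self):
        seq = ch.CodingSequence(id="x", nucleotides="ATGAAATAA")
        counts = ch.count_codons(seq)
        assert counts.counts == {"ATG": 1, "AAA": 1, "TAA": 1}
        assert counts.total == 3

    @pytest.mark.parametrize("bad", ["", "ATGAAAATTT", "ATGAAT" + "ACGN"[0:3] + "N" * 3])
    def test_frame_and_alphabet_errors(self, bad):
        with pytest.raises((FrameError, AlphabetError)):
            ch.CodingSequence(id="bad", nucleotides=bad)

    def test_internal_stop_rejected_by_default(self):
        with pytest.raises(ValueError, match="internal stop"):
            ch.CodingSequence(id="x", nucleotides="ATGTAAAAA")
        ok = ch.CodingSequence(
            id="x", nucleotides="ATGTAAAAA", validate_internal_stops=False
        )
        assert ok.length_codons == 3


class TestRSCU:
    def test_uniform_family_is_unbiased(self, code):
        counts = make_counts({c: 1 for c in code.families["A"]})
        vec = ch.rscu(counts, code)
        assert all(vec.get(c) == pytest.approx(1.0) for c in code.families["A"])

    def test_hand_evaluated_ala_family(self, code):
        counts = make_counts({"GCT": 2, "GCA": 1})
        vec = ch.rscu(counts, code)
        assert vec.get("GCT") == pytest.approx(8 / 3)
        assert vec.get("GCA") == pytest.approx(4 / 3)
        assert vec.get("GCC") == 0 and vec.get("GCG") == 0

    def test_met_always_one_and_absent_families_flagged(self, code):
        vec = ch.rscu(make_counts({"ATG": 5}), code)
        assert vec.get("ATG") == 1.0
        assert "A" in vec.absent_aas and "M" not in vec.absent_aas
        with pytest.raises(KeyError):
            vec.get("GCT")  # absent family: no silent zero

    def test_family_sum_equals_degeneracy(self, code):
        seq = ch.random_cds(300, ch.random_weight_table(3), seed=11)
        vec = ch.rscu(ch.count_codons(seq), code)
        for aa, fam in code.families.items():
            if aa in vec.absent_aas:
                continue
            assert sum(vec.get(c) for c in fam) == pytest.approx(len(fam))

    def test_scale_invariance_of_rscu_and_w(self, code):
        base = {"GCT": 2, "GCA": 1, "AAA": 3, "AAG": 1}
        v1 = ch.rscu(make_counts(base), code)
        v7 = ch.rscu(make_counts({c: 7 * x for c, x in base.items()}), code)
        for c in base:
            assert v1.get(c) == pytest.approx(v7.get(c))


class TestRelativeAdaptiveness:
    def test_hand_evaluated(self, code):
        vec = ch.rscu(make_counts({"GCT": 2, "GCA": 1}), code)
        w = ch.relative_adaptiveness(vec, code)
        assert w.weights["GCT"] == 1.0
        assert w.weights["GCA"] == pytest.approx(0.5)
        assert w.weights["GCC"] == 0.0

    def test_equal_usage_gives_all_ones(self, code):
        vec = ch.rscu(make_counts({c: 4 for c in code.families["G"]}), code)
        w = ch.relative_adaptiveness(vec, code)
        assert all(w.weights[c] == 1.0 for c in code.families["G"])

    def test_absent_family_excluded(self, code):
        vec = ch.rscu(make_counts({"ATG": 1}), code)
        w = ch.relative_adaptiveness(vec, code)
        assert "GCT" not in w.weights and "A" in w.absent_aas


class TestGeometricIndex:
    def test_all_max_codons_score_one(self, chi_weights):
        seq = ch.max_index_recode("MKLVAEGH" * 5, chi_weights)
        assert ch.geometric_index(seq, chi_weights) == pytest.approx(1.0)

    def test_two_codon_hand_value(self, code):
        w = ch.WeightTable(weights={"AAA": 1.0, "AAG": 0.25}, label="toy")
        seq = ch.CodingSequence(id="x", nucleotides="AAAAAG")
        assert ch.geometric_index(seq, w) == pytest.approx(math.sqrt(0.25))

    def test_missing_weight_names_codon(self):
        w = ch.WeightTable(weights={"AAA": 1.0}, label="toy")
        seq = ch.CodingSequence(id="x", nucleotides="AAAGCT")
        with pytest.raises(ScoringError, match="GCT"):
            ch.geometric_index(seq, w)

    def test_epsilon_floor_vs_strict(self):
        w = ch.WeightTable(weights={"AAA": 1.0, "AAG": 0.0}, label="toy")
        seq = ch.CodingSequence(id="x", nucleotides="AAAAAG")
        assert ch.geometric_index(seq, w) == pytest.approx(math.sqrt(0.01))
        with pytest.raises(ScoringError, match="strict"):
            ch.geometric_index(seq, w, strict=True)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 30))
    def test_brute_force_log_space_oracle(self, seed, length):
        """Agrees to 1e-12 with a direct product over scored codons."""
        code = ch.standard_code()
        w = ch.random_weight_table(seed % 1000, min_w=0.05)
        seq = ch.random_cds(length, w, seed=seed)
        scored = [
            c for c in seq.codons
            if not code.is_stop(c) and len(code.family_of(c)) > 1
        ]
        if not scored:
            return
        prod = 1.0
        for c in scored:
            prod *= max(w.weights[c], w.epsilon_floor)
        expected = prod ** (1.0 / len(scored))
        assert ch.geometric_index(seq, w) == pytest.approx(expected, abs=1e-12)

    def test_monotone_under_lower_w_swap(self, code, chi_weights):
        seq = ch.max_index_recode("MKKLLVV", chi_weights)
        base = ch.geometric_index(seq, chi_weights)
        fam = code.family_of(seq.codons[1])
        worse = min(fam, key=lambda c: chi_weights.weights[c])
        swapped = seq.with_codons(
            [worse if i == 1 else c for i, c in enumerate(seq.codons)]
        )
        assert ch.geometric_index(swapped, chi_weights) <= base


def transcribed_enc(counts, code):
    """Independent literal transcription of the ENC formula (oracle)."""
    per_class = {}
    for aa, fam in code.families.items():
        k = len(fam)
        if k == 1:
            continue
        n = sum(counts.get(c) for c in fam)
        if n <= 1:
            continue
        s = sum((counts.get(c) / n) ** 2 for c in fam)
        per_class.setdefault(k, []).append((n * s - 1) / (n - 1))
    fs = {k: sum(v) / len(v) for k, v in per_class.items() if v}
    if set(fs) != {2, 3, 4, 6} or any(f <= 0 for f in fs.values()):
        return None
    return min(61.0, 2 + 9 / fs[2] + 1 / fs[3] + 5 / fs[4] + 3 / fs[6])


class TestENC:
    def test_single_codon_per_aa_gives_20(self, all_aa_parent):
        assert ch.enc(ch.count_codons(all_aa_parent)) == pytest.approx(20.0)

    def test_uniform_usage_gives_61(self, uniform_counts):
        assert ch.enc(uniform_counts) == pytest.approx(61.0)

    def test_direct_formula_arithmetic(self):
        assert ch.enc_from_homozygosity(0.5, 0.5, 0.5, 0.5) == pytest.approx(38.0)

    def test_uniform_homozygosities_give_61(self):
        assert ch.enc_from_homozygosity(1 / 2, 1 / 3, 1 / 4, 1 / 6) == pytest.approx(61.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_transcription(self, seed, code):
        w = ch.random_weight_table(seed, min_w=0.2)
        seq = ch.random_cds(250, w, seed=seed + 100)
        counts = ch.count_codons(seq)
        oracle = transcribed_enc(counts, code)
        if oracle is None:
            pytest.skip("degenerate sample for the oracle")
        assert ch.enc(counts, code) == pytest.approx(oracle, abs=1e-12)

    def test_range_invariant(self):
        for seed in range(6):
            w = ch.random_weight_table(seed)
            seq = ch.random_cds(120, w, seed=seed)
            val = ch.enc(ch.count_codons(seq))
            assert 20.0 <= val <= 61.0

    def test_missing_class_imputed_with_warning(self, code):
        # only 2-fold and 4-fold families observed
        counts = make_counts({"AAA": 5, "AAG": 1, "GCT": 4, "GCC": 2})
        with pytest.warns(UserWarning, match="imputed"):
            val = ch.enc(counts, code)
        assert 20.0 <= val <= 61.0


class TestNTEWeights:
    def test_constant_ratio_gives_all_ones(self, code):
        stai = ch.WeightTable(
            weights={c: 0.5 for c in code.sense_codons}, label="stai"
        )
        freq = {c: 1 / 61 for c in code.sense_codons}
        w = ch.nte_weights(stai, freq, code=code)
        assert all(v == pytest.approx(1.0) for v in w.weights.values())

    def test_hand_evaluated_two_codon_family(self, code):
        stai_w = {c: 0.3 for c in code.sense_codons}
        stai_w.update({"AAA": 0.8, "AAG": 0.4})
        freq = {c: 1 / 61 for c in code.sense_codons}
        freq.update({"AAA": 0.5, "AAG": 0.5})
        w = ch.nte_weights(ch.WeightTable(weights=stai_w, label="stai"), freq, code=code)
        # ratios {1.6, 0.8} normalize to {1, 0.5}
        assert w.weights["AAA"] == pytest.approx(1.0)
        assert w.weights["AAG"] == pytest.approx(0.5)

    def test_zero_frequency_strict_errors(self, code):
        stai = ch.WeightTable(weights={c: 0.5 for c in code.sense_codons}, label="s")
        freq = {c: 1 / 61 for c in code.sense_codons}
        freq["GCT"] = 0.0
        with pytest.raises(ScoringError, match="GCT"):
            ch.nte_weights(stai, freq, code=code)


class TestExpectedRSCU:
    def test_perfect_mode_indicator(self, code, chi_weights):
        vec = ch.expected_rscu(chi_weights, mode="perfect", code=code)
        for aa, fam in code.families.items():
            values = sorted((vec.get(c) for c in fam), reverse=True)
            assert values[0] == len(fam)
            assert all(v == 0 for v in values[1:])

    def test_tie_in_perfect_mode_errors(self, code):
        w = ch.WeightTable(
            weights={c: 1.0 for c in code.sense_codons}, label="flat"
        )
        with pytest.raises(ValueError, match="tied"):
            ch.expected_rscu(w, mode="perfect", code=code)

    def test_proportional_mode_sums_to_degeneracy(self, code, chi_weights):
        vec = ch.expected_rscu(chi_weights, mode="proportional", code=code)
        for aa, fam in code.families.items():
            assert sum(vec.get(c) for c in fam) == pytest.approx(len(fam))
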