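"""Allele windows, delta scores, and gain calling."""

import numpy as np
import pytest

from mucistarget.pwm import PWM, BackgroundModel, reverse_complement
from mucistarget.variant_scoring import (
    GenomicVariant,
    ReferenceMismatchError,
    delta_score,
    extract_allele_windows,
    score_variants_against_regulators,
    window_size_for_motif,
)

from .conftest import brute_force_score, random_dna, random_pwm_matrix

UNIFORM = BackgroundModel.uniform()


class TestWindowSizeRule:
    @pytest.mark.parametrize(
        "length, expected",
        [(1, 20), (10, 20), (15, 20), (16, 30), (20, 30), (25, 30), (26, 60), (40, 60)],
    )
    def test_rule(self, length, expected):
        assert window_size_for_motif(length) == expected

    def test_whole_rule_table(self):
        expected = {n: 20 if n <= 15 else 30 if n <= 25 else 60 for n in range(1, 41)}
        assert {n: window_size_for_motif(n) for n in range(1, 41)} == expected

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            window_size_for_motif(0)


class TestExtractAlleleWindows:
    genome = {"chr1": "ACGT" * 25}  # 100 bp

    def test_snv_window_lengths(self):
        v = GenomicVariant("chr1", 50, "C", "T", "v1")  # genome[49] == 'C'
        ref_seq, mut_seq = extract_allele_windows(self.genome, v, 20)
        assert len(ref_seq) == 20 and len(mut_seq) == 20
        diffs = [i for i, (a, b) in enumerate(zip(ref_seq, mut_seq)) if a != b]
        assert diffs == [9]  # left flank gets the smaller half

    def test_insertion_lengthens_mutant(self):
        v = GenomicVariant("chr1", 50, "C", "CAA", "v2")
        ref_seq, mut_seq = extract_allele_windows(self.genome, v, 20)
        assert len(mut_seq) == len(ref_seq) + 2

    def test_deletion_shortens_mutant(self):
        v = GenomicVariant("chr1", 47, "GT", "G", "v3")  # genome[46:48] == "GT"
        ref_seq, mut_seq = extract_allele_windows(self.genome, v, 20)
        assert len(ref_seq) == 21 and len(mut_seq) == 20

    def test_ref_mismatch_fails_fast(self):
        v = GenomicVariant("chr1", 50, "A", "G", "bad")
        with pytest.raises(ReferenceMismatchError, match="bad"):
            extract_allele_windows(self.genome, v, 20)

    def test_contig_edge_truncates(self):
        v = GenomicVariant("chr1", 2, "C", "A", "edge")
        ref_seq, _ = extract_allele_windows(self.genome, v, 20)
        assert ref_seq.startswith("ACG") and len(ref_seq) < 20


class TestDeltaScore:
    def test_identity_has_zero_delta(self):
        rng = np.random.default_rng(0)
        pwm = PWM("p", random_pwm_matrix(rng, 6))
        seq = random_dna(rng, 20)
        ds = delta_score(pwm, UNIFORM, seq, seq)
        assert ds.delta == 0.0 and not ds.is_gain

    def test_consensus_gain_extremes(self):
        anti = "ACGTACGT"  # RC palindrome: scores exactly 0
        mat = np.full((8, 4), 0.9 / 3)
        for i, b in enumerate(anti):
            mat[i, "ACGT".index(b)] = 0.1
        pwm = PWM("x", mat)
        ref_seq = anti
        mut_seq = "TT" + pwm.consensus() + "TT"
        ds = delta_score(pwm, UNIFORM, ref_seq, mut_seq)
        assert ds.wild_score == pytest.approx(0.0, abs=1e-12)
        assert ds.mutant_score == pytest.approx(1.0, abs=1e-12)
        assert ds.delta == pytest.approx(1.0, abs=1e-12)
        assert ds.is_gain

    @pytest.mark.parametrize(
        "wild, mutant, expected",
        [
            (0.87, 0.95, False),  # delta 0.08 < 0.1 despite mutant >= 0.90
            (0.80, 0.95, True),
            (0.50, 0.89, False),  # mutant below 0.90 despite large delta
            (0.80, 0.90, True),   # both thresholds inclusive
            (0.80, 0.9999999, True),
        ],
    )
    def test_both_gain_conditions_required(self, wild, mutant, expected):
        from mucistarget.variant_scoring import call_gain

        assert call_gain(wild, mutant) is expected

    def test_gain_grid_monotone_in_both_scores(self):
        from mucistarget.variant_scoring import call_gain

        grid = np.round(np.linspace(0, 1, 21), 3)
        for wild in grid:
            for mutant in grid:
                g = call_gain(wild, mutant)
                # lowering wild or raising mutant never turns a gain off
                if g:
                    assert call_gain(max(wild - 0.05, 0), mutant)
                    assert call_gain(wild, min(mutant + 0.05, 1.0))

    def test_exchange_property_negates_delta(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            pwm = PWM("e", random_pwm_matrix(rng, 6, peaked=True))
            a, b = random_dna(rng, 20), random_dna(rng, 20)
            fwd = delta_score(pwm, UNIFORM, a, b)
            rev = delta_score(pwm, UNIFORM, b, a)
            assert fwd.delta == pytest.approx(-rev.delta, abs=1e-12)

    def test_strand_symmetry_of_delta(self):
        rng = np.random.default_rng(2)
        pwm = PWM("s", random_pwm_matrix(rng, 7, peaked=True))
        a, b = random_dna(rng, 21), random_dna(rng, 23)
        fwd = delta_score(pwm, UNIFORM, a, b)
        rev = delta_score(pwm, UNIFORM, reverse_complement(a), reverse_complement(b))
        assert fwd.wild_score == pytest.approx(rev.wild_score, abs=1e-12)
        assert fwd.mutant_score == pytest.approx(rev.mutant_score, abs=1e-12)


class TestScoreVariantsAgainstRegulators:
    def test_empty_variants_empty_result(self):
        rng = np.random.default_rng(3)
        pwm = PWM("m", random_pwm_matrix(rng, 8, peaked=True))
        out = score_variants_against_regulators([], [pwm], {"chr1": "ACGT" * 10}, UNIFORM)
        assert out == []

    def test_empty_motif_set_rejected(self):
        with pytest.raises(ValueError):
            score_variants_against_regulators([], [], {"chr1": "ACGT" * 10}, UNIFORM)

    def test_multiple_motifs_can_gain_on_one_variant(self):
        # five motifs share a consensus created by a single SNV
        rng = np.random.default_rng(4)
        core = "ACGGTTAC"
        motifs = []
        for i in range(5):
            mat = np.full((8, 4), 0.01)
            for j, b in enumerate(core):
                mat[j] = 0.01
                mat[j, "ACGT".index(b)] = 0.97
                mat[j] /= mat[j].sum()
            motifs.append(PWM(f"m{i}", mat))
        broken = "ACGGTTAA"  # last base breaks all five
        genome = {"chr1": random_dna(rng, 100) + broken + random_dna(rng, 100)}
        v = GenomicVariant("chr1", 108, "A", "C", "fix")
        gains = score_variants_against_regulators([v], motifs, genome, UNIFORM)
        assert {d.motif_id for _, d in gains} == {f"m{i}" for i in range(5)}

    def test_raising_thresholds_never_adds_gains(self):
        rng = np.random.default_rng(5)
        pwm = PWM("t", random_pwm_matrix(rng, 8, peaked=True))
        genome = {"chr1": random_dna(rng, 2000)}
        variants = []
        for i in range(40):
            pos0 = 50 + i * 45
            ref = genome["chr1"][pos0]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            variants.append(GenomicVariant("chr1", pos0 + 1, ref, alt, f"v{i}"))
        loose = score_variants_against_regulators(
            [v for v in variants], [pwm], genome, UNIFORM,
            min_mutant_score=0.5, min_delta=0.01,
        )
        tight = score_variants_against_regulators(
            [v for v in variants], [pwm], genome, UNIFORM,
            min_mutant_score=0.9, min_delta=0.1,
        )
        assert len(tight) <= len(loose)
        assert {(v.variant_id, d.motif_id) for v, d in tight} <= {
            (v.variant_id, d.motif_id) for v, d in loose
        }

    def test_scores_match_explicit_window_rescoring(self):
        rng = np.random.default_rng(6)
        genome = {"chr1": random_dna(rng, 3000)}
        bg = BackgroundModel(np.array([0.3, 0.2, 0.2, 0.3]))
        for _ in range(100):
            L = int(rng.integers(4, 12))
            pwm = PWM("o", random_pwm_matrix(rng, L, peaked=True))
            pos0 = int(rng.integers(100, 2900))
            ref = genome["chr1"][pos0]
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            v = GenomicVariant("chr1", pos0 + 1, ref, alt, "v")
            window = max(20 if L <= 15 else 30, L)
            ref_seq, mut_seq = extract_allele_windows(genome, v, window)
            ds = delta_score(pwm, bg, ref_seq, mut_seq)
            assert ds.wild_score == pytest.approx(
                brute_force_score(pwm.matrix, list(bg.frequencies), ref_seq), abs=1e-9
            )
            assert ds.mutant_score == pytest.approx(
                brute_force_score(pwm.matrix, list(bg.frequencies), mut_seq), abs=1e-9
            )


class TestGenomicVariant:
    def test_class_derivation(self):
        assert GenomicVariant("1", 5, "A", "G").variant_class == "SNV"
        assert GenomicVariant("1", 5, "A", "AT").variant_class == "insertion"
        assert GenomicVariant("1", 5, "AT", "A").variant_class == "deletion"

    def test_invalid_alleles_rejected(self):
        with pytest.raises(ValueError):
            GenomicVariant("1", 5, "A", "A")
        with pytest.raises(ValueError):
            GenomicVariant("1", 0, "A", "G")
        with pytest.raises(ValueError):
            GenomicVariant("1", 5, "A", "")
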