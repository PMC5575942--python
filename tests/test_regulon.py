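"""Recovery-AUC / NES motif enrichment and master-regulator filtering."""

import math

import numpy as np
import pandas as pd
import pytest

from mucistarget.regulon import (
    GeneSignature,
    MotifRankingDatabase,
    enriched_motifs,
    master_regulators,
    nes_scores,
    recovery_auc,
)


def _random_db(rng, n_motifs=20, n_genes=200, planted_sig=None):
    """Random-permutation rankings; motif 0 optionally concentrates a signature."""
    genes = [f"G{i:03d}" for i in range(n_genes)]
    ranks = np.stack([rng.permutation(n_genes) + 1 for _ in range(n_motifs)])
    if planted_sig is not None:
        row = np.empty(n_genes, dtype=int)
        sig_idx = [genes.index(g) for g in planted_sig]
        other = [i for i in range(n_genes) if genes[i] not in set(planted_sig)]
        row[sig_idx] = rng.permutation(len(sig_idx)) + 1
        row[other] = rng.permutation(len(other)) + len(sig_idx) + 1
        ranks[0] = row
    return MotifRankingDatabase(
        pd.DataFrame(ranks, index=[f"M{i:02d}" for i in range(n_motifs)], columns=genes)
    )


def _brute_force_auc(gene_ranks, signature, roc_fraction, n_genes):
    """Literal sum-of-recovery-curve oracle."""
    k_max = math.floor(roc_fraction * n_genes)
    sig_ranks = sorted(gene_ranks[g] for g in signature)
    total = sum(sum(1 for r in sig_ranks if r <= k) for k in range(1, k_max + 1))
    ideal = sum(min(k, len(sig_ranks)) for k in range(1, k_max + 1))
    return total / ideal


class TestRecoveryAuc:
    def test_hand_worked_small_example(self):
        # G=10, roc 0.5 -> k_max=5; signature at ranks {1, 4}:
        # r = (1,1,1,2,2) sums to 7; ideal = 1+2+2+2+2 = 9
        ranks = {f"g{i}": i for i in range(1, 11)}
        auc = recovery_auc(ranks, ["g1", "g4"], roc_fraction=0.5, n_genes=10)
        assert auc == pytest.approx(7 / 9)

    def test_top_ranked_signature_attains_maximum(self):
        ranks = {f"g{i}": i for i in range(1, 101)}
        sig = [f"g{i}" for i in range(1, 4)]
        assert recovery_auc(ranks, sig, roc_fraction=0.1, n_genes=100) == 1.0

    def test_signature_below_cutoff_scores_zero(self):
        ranks = {f"g{i}": i for i in range(1, 101)}
        sig = [f"g{i}" for i in range(50, 60)]
        assert recovery_auc(ranks, sig, roc_fraction=0.03, n_genes=100) == 0.0

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(50, 300))
            perm = rng.permutation(n) + 1
            ranks = {f"g{i}": int(perm[i]) for i in range(n)}
            sig = [f"g{i}" for i in rng.choice(n, size=int(rng.integers(2, 20)), replace=False)]
            frac = float(rng.uniform(0.05, 0.5))
            assert recovery_auc(ranks, sig, frac, n) == pytest.approx(
                _brute_force_auc(ranks, sig, frac, n), abs=1e-12
            )

    def test_improving_a_rank_never_lowers_auc(self):
        rng = np.random.default_rng(1)
        n = 100
        perm = list(rng.permutation(n) + 1)
        ranks = {f"g{i}": perm[i] for i in range(n)}
        sig = ["g0", "g1", "g2"]
        base = recovery_auc(ranks, sig, 0.2, n)
        # move g0 to rank 1, swapping with whoever held it
        holder = next(g for g, r in ranks.items() if r == 1)
        ranks[holder], ranks["g0"] = ranks["g0"], 1
        assert recovery_auc(ranks, sig, 0.2, n) >= base

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError):
            recovery_auc({"g": 1}, [], 0.1, 10)


class TestNesScores:
    def test_all_equal_aucs_give_zero(self):
        assert set(nes_scores({"a": 0.3, "b": 0.3, "c": 0.3}).values()) == {0.0}

    def test_hand_arithmetic_outlier(self):
        nes = nes_scores({"a": 0.0, "b": 0.0, "c": 0.0, "d": 1.0})
        assert nes["d"] == pytest.approx((1 - 0.25) / math.sqrt(3 / 16))
        assert nes["d"] == pytest.approx(1.732, abs=1e-3)

    def test_mean_is_zero(self):
        rng = np.random.default_rng(2)
        aucs = {f"m{i}": float(rng.random()) for i in range(50)}
        assert np.mean(list(nes_scores(aucs).values())) == pytest.approx(0.0, abs=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        aucs = {f"m{i}": float(rng.random()) for i in range(30)}
        scaled = {m: 0.2 * a + 3.0 for m, a in aucs.items()}
        n1, n2 = nes_scores(aucs), nes_scores(scaled)
        for m in aucs:
            assert n1[m] == pytest.approx(n2[m], abs=1e-9)

    def test_single_motif_rejected(self):
        with pytest.raises(ValueError):
            nes_scores({"only": 0.5})


class TestEnrichedMotifs:
    def test_planted_motif_recovered_first(self):
        rng = np.random.default_rng(4)
        sig_genes = [f"G{i:03d}" for i in rng.choice(200, size=20, replace=False)]
        db = _random_db(rng, planted_sig=sig_genes)
        sig = GeneSignature("s", frozenset(sig_genes))
        out = enriched_motifs(db, sig)
        assert out and out[0].motif_id == "M00" and out[0].nes >= 3

    def test_random_rankings_rarely_enrich(self):
        rng = np.random.default_rng(5)
        n_pass = 0
        for _ in range(20):
            db = _random_db(rng)
            sig = GeneSignature(
                "s", frozenset(f"G{i:03d}" for i in rng.choice(200, 20, replace=False))
            )
            n_pass += len(enriched_motifs(db, sig))
        assert n_pass <= 4  # ~1% of 400 motif tests

    def test_rank_threshold_zero_empties_leading_edges(self):
        rng = np.random.default_rng(6)
        sig_genes = [f"G{i:03d}" for i in range(20)]
        db = _random_db(rng, planted_sig=sig_genes)
        sig = GeneSignature("s", frozenset(sig_genes))
        out = enriched_motifs(db, sig, rank_threshold=0)
        assert all(not em.leading_edge_genes for em in out)

    def test_leading_edge_is_subset_of_signature(self):
        rng = np.random.default_rng(7)
        sig_genes = [f"G{i:03d}" for i in range(25)]
        db = _random_db(rng, planted_sig=sig_genes)
        out = enriched_motifs(db, GeneSignature("s", frozenset(sig_genes)))
        for em in out:
            assert em.leading_edge_genes <= frozenset(sig_genes)

    def test_dilution_with_random_motifs_keeps_planted_first(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            sig_genes = [f"G{i:03d}" for i in rng.choice(200, size=15, replace=False)]
            db = _random_db(rng, n_motifs=30, planted_sig=sig_genes)
            out = enriched_motifs(db, GeneSignature("s", frozenset(sig_genes)))
            assert out and out[0].motif_id == "M00"


class TestMasterRegulators:
    def test_filtering_rules(self):
        from mucistarget.regulon import EnrichedMotif

        enriched = [
            EnrichedMotif("m1", 0.9, 5.0, frozenset(), frozenset({"TFA"})),
            EnrichedMotif("m2", 0.8, 4.0, frozenset(), frozenset({"TFB"})),
            EnrichedMotif("m3", 0.7, 3.5, frozenset(), frozenset({"TFC"})),
            EnrichedMotif("m4", 0.6, 3.1, frozenset(), frozenset({"TFD"})),
        ]
        motif2tf = {"m1": {"TFA"}, "m2": {"TFB"}, "m3": {"TFC"}, "m4": {"TFD"}}
        expression = {"TFA": 1.2, "TFB": 0.9, "TFC": 1.5}  # TFD missing
        relevant = {"TFA", "TFB", "TFD"}  # TFC expressed but not relevant
        out = master_regulators(enriched, motif2tf, expression, relevant)
        assert [m.tf_symbol for m in out] == ["TFA"]
        assert out[0].motifs == frozenset({"m1"})
        assert out[0].expression_z == pytest.approx(1.2)

    def test_z_exactly_one_excluded(self):
        from mucistarget.regulon import EnrichedMotif

        enriched = [EnrichedMotif("m", 0.9, 5.0, frozenset(), frozenset({"TF1"}))]
        out = master_regulators(enriched, {"m": {"TF1"}}, {"TF1": 1.0}, {"TF1"})
        assert out == []

    def test_motifs_grouped_per_tf(self):
        from mucistarget.regulon import EnrichedMotif

        enriched = [
            EnrichedMotif("m1", 0.9, 5.0, frozenset(), frozenset({"TF1"})),
            EnrichedMotif("m2", 0.8, 4.0, frozenset(), frozenset({"TF1"})),
        ]
        out = master_regulators(
            enriched, {"m1": {"TF1"}, "m2": {"TF1"}}, {"TF1": 2.0}, {"TF1"}
        )
        assert len(out) == 1 and out[0].motifs == frozenset({"m1", "m2"})

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            master_regulators([], {}, {}, set())


class TestMotifRankingDatabase:
    def test_non_permutation_rejected(self):
        genes = [f"g{i}" for i in range(100)]
        ranks = np.tile(np.arange(1, 101), (3, 1))
        ranks[1, 0] = 5  # duplicate rank
        with pytest.raises(ValueError, match="permutation"):
            MotifRankingDatabase(pd.DataFrame(ranks, index=["a", "b", "c"], columns=genes))

    def test_small_universe_rejected(self):
        genes = [f"g{i}" for i in range(50)]
        ranks = np.tile(np.arange(1, 51), (2, 1))
        with pytest.raises(ValueError, match="100"):
            MotifRankingDatabase(pd.DataFrame(ranks, index=["a", "b"], columns=genes))

    def test_unmatched_signature_genes_dropped(self):
        rng = np.random.default_rng(8)
        db = _random_db(rng)
        sig = GeneSignature("s", frozenset({"G000", "G001", "NOT_A_GENE"}))
        assert db.match_signature(sig) == frozenset({"G000", "G001"})
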