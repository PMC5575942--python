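"""Sample-specific master-regulator inference by ranking-recovery motif enrichment.

Given a gene signature (over-expressed genes, Z > 1) and a database of
whole-genome gene rankings per motif, each motif's recovery AUC over the top
fraction of its ranking is standardized across the motif collection into a
normalized enrichment score (NES). Motifs with NES >= 3 (default) are
enriched; their annotated transcription factors, filtered for own
over-expression and cancer-type relevance, are the sample's master regulators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_NES_THRESHOLD = 3.0
DEFAULT_ROC_FRACTION = 0.03
DEFAULT_RANK_THRESHOLD = 5000
DEFAULT_EXPRESSION_Z = 1.0


@dataclass(frozen=True)
class GeneSignature:
    sample_id: str
    genes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))
        if not self.genes:
            raise ValueError("gene signature is empty")


class MotifRankingDatabase:
    """Per-motif rankings of a common gene universe (rank 1 = best).

    ``ranks`` is a motifs x genes integer DataFrame; each row must be a
    permutation of 1..G.
    """

    def __init__(self, ranks: pd.DataFrame):
        ranks = ranks.copy()
        ranks.columns = [str(c).upper() for c in ranks.columns]
        g = ranks.shape[1]
        if g < 100:
            raise ValueError("gene universe must have >= 100 genes for meaningful NES")
        expected = np.arange(1, g + 1)
        arr = ranks.to_numpy()
        sorted_rows = np.sort(arr, axis=1)
        bad = np.nonzero((sorted_rows != expected).any(axis=1))[0]
        if bad.size:
            raise ValueError(
                f"motif {ranks.index[bad[0]]!r}: ranks are not a permutation of 1..{g}"
            )
        self.ranks = ranks

    @property
    def motif_ids(self) -> list:
        return list(self.ranks.index)

    @property
    def gene_universe(self) -> list:
        return list(self.ranks.columns)

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[1]

    def match_signature(self, signature: GeneSignature) -> frozenset:
        """Signature genes present in the universe; unmatched are dropped with a log line."""
        universe = set(self.gene_universe)
        matched = signature.genes & universe
        dropped = len(signature.genes) - len(matched)
        if dropped:
            log.info(
                "signature %s: dropped %d/%d genes absent from the ranking universe",
                signature.sample_id,
                dropped,
                len(signature.genes),
            )
        return frozenset(matched)


@dataclass(frozen=True)
class EnrichedMotif:
    motif_id: str
    auc: float
    nes: float
    leading_edge_genes: frozenset
    tfs: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class MasterRegulator:
    tf_symbol: str
    motifs: frozenset
    expression_z: float
    cancer_relevant: bool


def recovery_auc(gene_ranks, signature_genes, roc_fraction: float = DEFAULT_ROC_FRACTION,
                 n_genes: int | None = None) -> float:
    """AUC of the discrete recovery curve over the top ``roc_fraction`` of a ranking.

    ``gene_ranks`` maps gene -> rank (1-based) for one motif. The recovery
    curve r(k) counts signature genes with rank <= k for k = 1..floor(f*G);
    the AUC is sum_k r(k) normalized by its maximum (all signature genes at
    the very top), so it lies in [0, 1].
    """
    if not (0 < roc_fraction < 1):
        raise ValueError("roc_fraction must be in (0, 1)")
    if not signature_genes:
        raise ValueError("empty signature")
    if n_genes is None:
        n_genes = len(gene_ranks)
    k_max = int(math.floor(roc_fraction * n_genes))
    if k_max < 1:
        raise ValueError("roc_fraction * n_genes < 1: recovery curve is empty")

    sig_ranks = np.array([gene_ranks[g] for g in signature_genes if g in gene_ranks])
    s = len(sig_ranks)
    if s == 0:
        raise ValueError("no signature gene present in the ranking")
    # sum over k of r(k): each hit at rank r contributes (k_max - r + 1)
    hits = sig_ranks[sig_ranks <= k_max]
    total = float(np.sum(k_max - hits + 1))
    # ideal: hits at ranks 1..min(s, k_max)
    m = min(s, k_max)
    ideal = float(m * k_max - (m * (m - 1)) // 2)
    return total / ideal


def nes_scores(aucs: dict) -> dict:
    """Standardize per-motif AUCs (population sd) into normalized enrichment scores."""
    if len(aucs) < 2:
        raise ValueError("NES is undefined for fewer than 2 motifs")
    motif_ids = list(aucs)
    values = np.array([aucs[m] for m in motif_ids], dtype=float)
    sd = float(values.std())  # population sd
    if sd == 0:
        return {m: 0.0 for m in motif_ids}
    mean = float(values.mean())
    return {m: (aucs[m] - mean) / sd for m in motif_ids}


def enriched_motifs(
    db: MotifRankingDatabase,
    signature: GeneSignature,
    nes_threshold: float = DEFAULT_NES_THRESHOLD,
    roc_fraction: float = DEFAULT_ROC_FRACTION,
    rank_threshold: int = DEFAULT_RANK_THRESHOLD,
    motif2tf: dict | None = None,
) -> list:
    """Motifs enriched in the signature (NES >= threshold), best first.

    Each enriched motif carries its leading edge: the signature genes ranked
    at or above ``rank_threshold`` in that motif's ranking (the inferred
    regulon members). ``motif2tf`` maps motif_id -> iterable of TF symbols.
    """
    matched = db.match_signature(signature)
    if not matched:
        raise ValueError(f"signature {signature.sample_id} shares no genes with the database")
    genes = list(matched)
    rank_matrix = db.ranks[genes]  # motifs x matched signature genes
    g = db.n_genes
    k_max = int(math.floor(roc_fraction * g))
    arr = rank_matrix.to_numpy()
    s = len(genes)
    m_ideal = min(s, k_max)
    ideal = float(m_ideal * k_max - (m_ideal * (m_ideal - 1)) // 2)
    contrib = np.where(arr <= k_max, k_max - arr + 1, 0)
    aucs = dict(zip(db.motif_ids, contrib.sum(axis=1) / ideal))
    nes = nes_scores(aucs)

    motif2tf = motif2tf or {}
    out = []
    for motif_id in db.motif_ids:
        if nes[motif_id] < nes_threshold:
            continue
        row = rank_matrix.loc[motif_id]
        leading = frozenset(gene for gene in genes if row[gene] <= rank_threshold)
        out.append(
            EnrichedMotif(
                motif_id=motif_id,
                auc=float(aucs[motif_id]),
                nes=float(nes[motif_id]),
                leading_edge_genes=leading,
                tfs=frozenset(motif2tf.get(motif_id, ())),
            )
        )
    out.sort(key=lambda em: (-em.nes, em.motif_id))
    return out


def master_regulators(
    enriched: list,
    motif2tf: dict,
    expression: dict,
    relevant_genes,
    min_expression_z: float = DEFAULT_EXPRESSION_Z,
) -> list:
    """TFs behind enriched motifs that are themselves over-expressed and cancer-relevant.

    A TF missing from the expression table is treated as not expressed (logged).
    """
    if not motif2tf:
        raise ValueError("motif -> TF annotation table is empty")
    relevant = {g.upper() for g in relevant_genes}
    expression = {g.upper(): z for g, z in expression.items()}

    tf_motifs: dict = {}
    for em in enriched:
        for tf in motif2tf.get(em.motif_id, ()):
            tf_motifs.setdefault(tf.upper(), set()).add(em.motif_id)

    out = []
    for tf in sorted(tf_motifs):
        if tf not in expression:
            log.info("TF %s absent from expression table; treated as not expressed", tf)
            continue
        z = expression[tf]
        if z <= min_expression_z:
            continue
        if tf not in relevant:
            continue
        out.append(
            MasterRegulator(
                tf_symbol=tf,
                motifs=frozenset(tf_motifs[tf]),
                expression_z=float(z),
                cancer_relevant=True,
            )
        )
    return out
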