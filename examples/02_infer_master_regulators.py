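"""Infer master regulators from a gene signature by ranking-recovery enrichment.

Builds a 500-gene x 20-motif ranking database in which one motif ("the MYB
motif") ranks a 30-gene over-expression signature at the very top, runs the
recovery-AUC / NES enrichment, and applies the expression + relevance filters.
"""

import numpy as np
import pandas as pd

from mucistarget.regulon import (
    GeneSignature,
    MotifRankingDatabase,
    enriched_motifs,
    master_regulators,
)

rng = np.random.default_rng(0)
genes = [f"G{i:03d}" for i in range(500)]
signature_genes = [genes[i] for i in rng.choice(500, size=30, replace=False)]

ranks = np.stack([rng.permutation(500) + 1 for _ in range(20)])
# motif 0 concentrates the signature in its top ranks; the rest are random
row = np.empty(500, dtype=int)
sig_idx = [genes.index(g) for g in signature_genes]
other_idx = [i for i in range(500) if genes[i] not in set(signature_genes)]
row[sig_idx] = rng.permutation(30) + 1
row[other_idx] = rng.permutation(470) + 31
ranks[0] = row

db = MotifRankingDatabase(
    pd.DataFrame(ranks, index=[f"motif_{i:02d}" for i in range(20)], columns=genes)
)
motif2tf = {"motif_00": {"MYB"}, "motif_01": {"ZNF1"}}
signature = GeneSignature("sampleA", frozenset(signature_genes))

enriched = enriched_motifs(db, signature, motif2tf=motif2tf)
print("enriched motifs (NES >= 3):")
for em in enriched:
    print(f"  {em.motif_id}: AUC {em.auc:.3f}, NES {em.nes:.2f}, "
          f"{len(em.leading_edge_genes)} leading-edge genes, TFs {sorted(em.tfs)}")

# MYB is over-expressed (Z = 1.8) and on the cancer-relevant list -> master regulator
expression = {"MYB": 1.8, "ZNF1": 0.2}
masters = master_regulators(enriched, motif2tf, expression, relevant_genes={"MYB"})
for m in masters:
    print(f"master regulator: {m.tf_symbol} (Z = {m.expression_z}), motifs {sorted(m.motifs)}")
# Only the planted motif clears NES >= 3; its TF passes the Z > 1 and
# relevance filters, so MYB is called a master regulator of this sample.
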