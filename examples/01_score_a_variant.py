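"""Delta-score a single non-coding variant against a transcription-factor motif.

Builds an 8-bp MYB-like motif and a toy genome in which an insertion restores
the motif's consensus, then scores the reference and mutant alleles.
"""

import numpy as np

from mucistarget.pwm import PWM, BackgroundModel
from mucistarget.variant_scoring import (
    GenomicVariant,
    delta_score,
    extract_allele_windows,
    window_size_for_motif,
)

# a sharply defined motif: consensus CAGTTGGT
consensus = "CAGTTGGT"
matrix = np.full((8, 4), 0.01)
for i, base in enumerate(consensus):
    matrix[i, "ACGT".index(base)] = 0.97
pwm = PWM("MYB_like", matrix, tf_annotations={"MYB"})

# genome carries the motif with its middle three bases missing (CAGTT..GT -> CAGGT)
flank5, flank3 = "ATTGCCATAG", "CCTATTGACA"
genome = {"chr1": flank5 + "CAGGT" + flank3}

# the insertion of TTG after position 13 restores the full consensus site
variant = GenomicVariant("chr1", 13, ref_allele="G", alt_allele="GTTG", variant_id="ins1")

window = window_size_for_motif(pwm.length)  # 20 bp for motifs of <= 15 bp
bg = BackgroundModel.uniform()
ref_seq, mut_seq = extract_allele_windows(genome, variant, window)
result = delta_score(pwm, bg, ref_seq, mut_seq, variant_id=variant.variant_id)

print(f"motif length {pwm.length} bp -> scan window {window} bp")
print(f"reference window: {ref_seq}")
print(f"mutant window:    {mut_seq}")
print(f"wild-type score:  {result.wild_score:.3f}")
print(f"mutant score:     {result.mutant_score:.3f}")
print(f"delta:            {result.delta:.3f}")
print(f"gain call:        {result.is_gain}  (requires mutant >= 0.90 and delta >= 0.1)")
# The mutant allele completes the consensus, so its window scores 1.0; the
# broken reference site scores well below, and the variant is called a
# candidate binding-site gain for MYB.
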