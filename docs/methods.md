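# Methods

This note documents the models and statistics implemented in `mucistarget`,
the defaults and why they were chosen, what the synthetic data emulate, and
the package's known limitations.

## PWM scoring

A motif is a position-probability matrix over (A, C, G, T) with length ≥ 4.
Scoring a sequence window:

- A zero-order background model is used; by default it is estimated once per
  run from the supplied genome FASTA (mononucleotide frequencies with a
  pseudocount of 1). A uniform background is available for sequence-only use.
- The log-odds matrix is `ln(max(p, floor) / bg)` with `floor = 0.001`, so
  zero probabilities never produce −∞. The pseudocount for count matrices is
  1.0. Both values are exposed as parameters.
- Every offset on both strands is scanned; the best raw sum is normalized by
  the matrix's achievable range: `(best − min_raw) / (max_raw − min_raw)`
  where `min_raw`/`max_raw` are the column-wise minimum/maximum sums. The
  score is clamped to [0, 1]. A degenerate constant matrix (zero range)
  scores 0 with a logged warning.
- `N` bases contribute the worst case `ln(floor / max(bg))`, so N-rich
  windows cannot clear the gain threshold spuriously. Soft-masked
  (lowercase) bases are uppercased and scored normally, since non-coding
  variants are scored regardless of repeat masking.
- Note that because both strands are scanned, the per-column-argmin
  ("anti-consensus") sequence attains score 0 exactly only when it is its
  own reverse complement; otherwise the opposite strand scores above the
  minimum. The consensus always attains 1 exactly.

## Variant windows and gain calls

Scan windows follow the motif length: 20 bp (≤ 15 bp motifs), 30 bp
(16–25 bp), 60 bp (> 25 bp). The window is anchored on the start of the REF
span; for a window of w bp the left flank is `(w−1)//2` bp (the smaller
half) so the full ALT allele always lies inside. Windows truncated at contig
edges are scored as-is with a warning; a REF/genome mismatch is a hard
error naming the variant.

A gain requires mutant score ≥ 0.90 **and** delta ≥ 0.1. Comparisons are
inclusive with a 1e-9 tolerance so binary floating-point cannot flip a
boundary case (e.g. 0.90 − 0.80 must count as a delta of 0.1). Each PWM
annotated to a TF is scored independently; a gain for any of a TF's motifs
counts as a gain for that TF. Loss calls (wild ≥ 0.90, delta ≤ −0.1) are
implemented behind a flag and off by default: the pipeline targets
gain-of-function events. Overlapping variants are scored independently,
never as joint haplotypes.

## Master-regulator inference

For one signature S (genes with expression Z > 1, matched case-insensitively
against the ranking universe; unmatched genes are dropped and counted in the
log) and a database of per-motif rankings (each row a permutation of 1..G):

- Recovery AUC over the top fraction f = 0.03: with k_max = ⌊f·G⌋ and
  r(k) = |{g ∈ S : rank(g) ≤ k}|, `AUC = Σ_k r(k) / Σ_k min(k, |S|)`. The
  denominator is the ideal curve (all signature genes on top), so AUC ∈ [0, 1].
- NES is the AUC standardized across the motif collection with the
  population standard deviation (with thousands of motifs the sample/population
  distinction is negligible; population is used for reproducibility). All
  NES of a run sum to zero; NES is invariant under affine rescaling of AUCs.
- Motifs with NES ≥ 3 are enriched; their leading edge is the signature
  genes ranked ≤ 5000 (or G, whichever is smaller) in that motif's ranking.
- TFs annotated to enriched motifs become master regulators iff their own
  expression Z > 1 and they appear in the cancer-relevant ∪ driver gene
  lists. TFs absent from the expression table are treated as not expressed
  and logged.

A universe of ≥ 100 genes is required; below that the NES standardization is
meaningless. When several ranking databases are used, NES is computed per
database and the maximum per motif kept.

## Variant and target filters

- Call-quality filters (inclusive): depth ≥ 10, alt-supporting reads ≥ 5,
  VAF ≥ 0.20. Records lacking a VAF skip that one threshold with a warning,
  matching platforms that do not report it.
- Coding variants are removed by any overlap of the REF span with
  protein-coding exon intervals (0-based half-open).
- dbSNP flagging is allele-aware (chrom, pos, ref, alt); position-only
  matching would over-flag somatic variants. The dbSNP track is scored by
  the identical pipeline and reported separately from the mutation track.
- Variants are assigned to every same-chromosome gene whose TSS lies within
  1 Mb of the REF span (distance is the minimum over the span; set
  semantics, no tie-breaking). This replaces GREAT's basal-plus-extension
  domains with symmetric all-TSS assignment — the downstream TAD filter
  subsumes the domain logic. Distance is measured to the TSS, not the gene
  body, consistent with the regulatory-space interpretation.
- Target filter: expression Z > 1 AND membership in the relevant ∪ driver
  lists.
- TAD co-localization: for each TAD sample, the pair passes if one interval
  contains both the variant position and the target TSS; the candidate
  records the supporting sample set, and with TAD filtering enabled
  (default) an empty set removes the pair. TAD filtering precedes the
  evidence layers.

All internal intervals are 0-based half-open; VCF positions are 1-based and
converted exactly once at the I/O boundary. Chromosome names are harmonized
to the genome FASTA's convention ("chr1" vs "1") at load time.

## Evidence layers

**Peaks.** Peak intervals closer than 350 bp are merged before overlap.
A candidate is in-peak if its REF span intersects any interval
(half-open), flagged per mark (H3K27ac vs TF ChIP). Enrichment of
candidates in peaks is an upper-tail hypergeometric test P(X ≥ k) with the
universe N defined as all scored variants of the track (mutations and SNPs
tested within their own track) and m of them in peaks; the universe choice
is a package convention, exposed in the output table alongside k, K, m, N.

**Allele-specific expression.** Het-SNP rows (gene, snp, ref reads,
alt reads) are filtered to ≥ 5 reads per allele and minor fraction ≥ 0.10.
Per gene, each SNP is pseudo-phased to its major allele; with
M = Σ max(ref, alt) out of T total reads, the p-value is
P(Σ max(Xᵢ, nᵢ−Xᵢ) ≥ M) under Xᵢ ~ Binomial(nᵢ, ½). This null is evaluated
exactly by convolution of the per-SNP max-statistic distributions for
totals up to 4000 reads, and by 10,000 seeded Monte Carlo draws above that
(with an add-one correction keeping the estimate a valid p-value). Testing
against this null — rather than Binomial(T, ½) — is essential: pseudo-phasing
inflates the naive test's rejection rate severalfold under a balanced null.
Genes are flagged after Benjamini–Hochberg adjustment when padj ≤ 0.05 and
the estimated major-allele fraction is ≥ 0.6; candidates inherit the flag
of their target gene.

This one-sample test is a deliberate simplification of MBASED: no
overdispersion (beta-binomial) parameter is estimated, and agreement with
MBASED's numerical output is not claimed — only the same decision
thresholds. With shallow coverage and strong imbalance the 5-reads-per-allele
filter can censor the most imbalanced SNPs; deeper counts avoid this.

## Synthetic data

The generator fabricates a complete, self-consistent dataset around planted
cis-GoF events: a random genome (default one 400 kb chromosome, GC 0.41),
500 evenly spaced gene TSSs, 50 motifs (8–12 bp, dominant base probability
0.97), a 40-gene signature at Z = 2 with all other genes truncated below
Z = 1, a ranking database in which each planted motif ranks the signature
on top and all other motifs are random permutations, 67 background SNVs plus
8 dbSNP-annotated SNPs, per-sample TADs, an H3K27ac peak over each planted
variant, and allele counts realizing per-gene true major-allele fractions
(targets at 0.8). The 500 × 50 ranking matches the package's toy-database
convention; the default planted event is an insertion 7.5 kb upstream of
its target, echoing the classic leukemia enhancer-insertion geometry.

Planting is verification-in-the-loop: the mutant window must score ≥ 0.90
with delta ≥ 0.1 while the reference window stays below 0.8, with flanks
redrawn up to 1000 times (failure raises). For SNV events the planted motif
is rebuilt to concentrate its information in one column, since a single
base change cannot span a 0.2 score range in a uniformly peaked matrix.
Background variants are rejection-sampled away from exons, planted sites,
and any motif gain for a planted TF; rejection counts are logged. Only
planted TFs appear on the relevant list, so no other motif can produce a
master regulator. A fixed seed makes every output file byte-identical
across regenerations.

What the fixtures do **not** emulate: realistic mutational signatures,
linkage, repeat structure, copy number, read-level noise, or motif
similarity within the collection. Passing the planted-recovery tests
demonstrates the pipeline's plumbing and threshold logic, not calling
performance on real tumor genomes.

## Problem sizes and determinism

The shipped tests and the acceptance script use: 20 generated datasets for
end-to-end recovery; 200 replicates of 50 motifs × 500 genes for the NES
null; 50 replicates for planted-motif recovery; 500 balanced and 200
imbalanced genes (5 SNPs × 20 reads) for ASE operating characteristics; 200
random (PWM, sequence) pairs against the brute-force scorer; and exhaustive
hypergeometric enumeration for universes up to N = 20 (N = 30 in the test
suite). All randomness flows from explicit seeds; reruns are byte-identical
(the run-config copy records absolute input paths and is excluded from
byte comparisons).

## Known limitations

- MotifLocator's exact numeric scale is not reproduced bit-for-bit; the
  normalization here is the documented convention (best-window log-odds,
  range-normalized per matrix), and thresholds are interpreted on that scale.
- Ranking databases are consumed, never built: no genome-wide motif scans,
  cross-species rank aggregation, or motif clustering.
- Somatic calling, read mapping, and peak calling are upstream of this tool.
- Allelic bias of regulatory activity (ChIP reads at the variant) is not
  computed: no input format carries ChIP read depths at variant positions.
  In matched datasets most in-peak candidates fall below usable ChIP
  coverage anyway.
- Multi-nucleotide haplotypes of nearby co-occurring variants are not scored
  jointly.
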