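"""Variant- and target-gene-level filters.

Covers post-call quality filtering (depth / mutation coverage / VAF),
exclusion of coding variants, dbSNP flagging (allele-aware), assignment of
non-coding variants to all gene TSSs within 1 Mb, over-expression and
cancer-relevance filters on target genes, and TAD co-localization of a
variant with its candidate target's promoter.

Internal intervals are 0-based half-open; variant positions follow the VCF
1-based convention and are converted via ``GenomicVariant.pos0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from intervaltree import IntervalTree

from .variant_scoring import GenomicVariant

log = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_MUTATION_COVERAGE = 5
DEFAULT_MIN_VAF = 0.20
DEFAULT_MAX_TSS_DISTANCE = 1_000_000


@dataclass(frozen=True)
class GeneModel:
    gene_symbol: str
    chrom: str
    tss: int  # 1-based position of the transcription start site
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"{self.gene_symbol}: TSS must be >= 1")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_symbol}: strand must be + or -")

    @property
    def tss0(self) -> int:
        return self.tss - 1


@dataclass(frozen=True)
class VariantCallRecord:
    """A variant with its call-quality metrics (depth, alt-supporting reads, VAF)."""

    variant: GenomicVariant
    depth: int
    mutation_coverage: int
    vaf: float | None = None

    def __post_init__(self) -> None:
        if self.depth < 0 or self.mutation_coverage < 0:
            raise ValueError(f"{self.variant.variant_id}: negative read counts")
        if self.mutation_coverage > self.depth:
            raise ValueError(
                f"{self.variant.variant_id}: mutation coverage exceeds depth"
            )


class TADSet:
    """Topologically associating domains of one sample; non-overlapping intervals."""

    def __init__(self, sample_id: str, intervals):
        self.sample_id = sample_id
        self.trees: dict = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(
                    f"TAD sample {sample_id}: interval {chrom}:{start}-{end} has start >= end"
                )
            tree = self.trees.setdefault(chrom, IntervalTree())
            if tree.overlap(start, end):
                raise ValueError(
                    f"TAD sample {sample_id}: overlapping intervals on {chrom} at {start}-{end}"
                )
            tree.addi(start, end)

    def containing_interval(self, chrom: str, pos0: int):
        """The (start, end) TAD containing a 0-based position, or None."""
        tree = self.trees.get(chrom)
        if tree is None:
            return None
        hits = tree.at(pos0)
        if not hits:
            return None
        iv = next(iter(hits))
        return (iv.begin, iv.end)


def _interval_trees(intervals) -> dict:
    trees: dict = {}
    for chrom, start, end in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def filter_variant_calls(
    records,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_mutation_coverage: int = DEFAULT_MIN_MUTATION_COVERAGE,
    min_vaf: float | None = DEFAULT_MIN_VAF,
) -> list:
    """Keep calls meeting all thresholds (inclusive).

    If a record has no VAF (e.g. a platform that does not report it) the VAF
    threshold is skipped for that record with a warning, matching a
    depth-and-coverage-only filtering arm.
    """
    kept = []
    warned = False
    for rec in records:
        if rec.depth < min_depth or rec.mutation_coverage < min_mutation_coverage:
            continue
        if min_vaf is not None:
            if rec.vaf is None:
                if not warned:
                    log.warning("records without VAF: VAF threshold skipped for them")
                    warned = True
            elif rec.vaf < min_vaf:
                continue
        kept.append(rec)
    return kept


def exclude_coding(variants, coding_exons) -> list:
    """Drop variants whose REF span overlaps any protein-coding exon interval."""
    trees = _interval_trees(coding_exons)
    out = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is not None and tree.overlap(v.pos0, v.end0):
            continue
        out.append(v)
    return out


def flag_dbsnp(variants, snp_lookup) -> list:
    """Set ``is_dbsnp`` by exact (chrom, pos, ref, alt) match against a dbSNP subset.

    Matching is allele-aware: the same position with a different ALT does not
    flag. Downstream, candidate somatic mutations are the is_dbsnp=False track.
    """
    lookup = set(snp_lookup)
    out = []
    for v in variants:
        hit = (v.chrom, v.pos, v.ref_allele, v.alt_allele) in lookup
        if hit != v.is_dbsnp:
            v = GenomicVariant(
                chrom=v.chrom,
                pos=v.pos,
                ref_allele=v.ref_allele,
                alt_allele=v.alt_allele,
                variant_id=v.variant_id,
                is_dbsnp=hit,
            )
        out.append(v)
    return out


def variant_tss_distance(variant: GenomicVariant, gene: GeneModel) -> int:
    """Minimum distance (bp) between the variant's REF span and the gene TSS."""
    t = gene.tss0
    if variant.pos0 <= t < variant.end0:
        return 0
    return min(abs(t - variant.pos0), abs(t - (variant.end0 - 1)))


def assign_to_genes(
    variants,
    genes,
    max_distance: int = DEFAULT_MAX_TSS_DISTANCE,
) -> list:
    """All (variant, gene, distance) pairs with TSS within ``max_distance`` bp.

    Symmetric, set-semantics assignment: every same-chromosome gene within
    range is paired; no tie-breaking.
    """
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs = []
    for v in variants:
        for g in by_chrom.get(v.chrom, ()):
            d = variant_tss_distance(v, g)
            if d <= max_distance:
                pairs.append((v, g, d))
    return pairs


def filter_target_genes(
    pairs,
    expression: dict,
    relevant_genes,
    driver_genes,
    min_expression_z: float = 1.0,
) -> list:
    """Keep pairs whose target is over-expressed (Z > 1) and relevant-or-driver.

    Genes missing from the expression table are treated as not over-expressed.
    """
    expression = {g.upper(): z for g, z in expression.items()}
    allowed = {g.upper() for g in relevant_genes} | {g.upper() for g in driver_genes}
    out = []
    missing = 0
    for v, g, d in pairs:
        symbol = g.gene_symbol.upper()
        z = expression.get(symbol)
        if z is None:
            missing += 1
            continue
        if z > min_expression_z and symbol in allowed:
            out.append((v, g, d))
    if missing:
        log.info("%d pairs dropped: target absent from expression table", missing)
    return out


def annotate_tad(variant: GenomicVariant, gene: GeneModel, tad_sets) -> frozenset:
    """Sample ids whose TAD map places the variant and the gene TSS in one TAD.

    An empty set means no sample supports co-localization (the pair fails the
    within-a-known-TAD filter).
    """
    supporting = set()
    for tads in tad_sets:
        iv = tads.containing_interval(variant.chrom, variant.pos0)
        if iv is None:
            continue
        if gene.chrom == variant.chrom and iv[0] <= gene.tss0 < iv[1]:
            supporting.add(tads.sample_id)
    return frozenset(supporting)
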