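"""Delta-scoring of variants for transcription-factor motif gains.

For each variant, a window around the mutation site is extracted from the
reference genome (window size depends on motif length: 20 bp for motifs of
15 bp or less, 30 bp for 16-25 bp, 60 bp above 25 bp), the mutant sequence is
built by substituting the ALT allele, and both are scored with the motif.
A gain call requires a mutant score >= 0.90 and a delta (mutant - wild-type)
>= 0.1 under the default thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .pwm import PWM, BackgroundModel, score_window

log = logging.getLogger(__name__)

DEFAULT_MIN_MUTANT_SCORE = 0.90
DEFAULT_MIN_DELTA = 0.1
#: tolerance for threshold comparisons so that e.g. 0.90 - 0.80 counts as 0.1
THRESHOLD_EPS = 1e-9


class ReferenceMismatchError(ValueError):
    """REF allele in a variant record disagrees with the genome sequence."""


@dataclass(frozen=True)
class GenomicVariant:
    """An SNV or indel in VCF convention (1-based ``pos`` of the first REF base)."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    variant_id: str = "."
    is_dbsnp: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1")
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or set(allele) - set("ACGT"):
                raise ValueError(
                    f"{self.variant_id}: alleles must be non-empty over A/C/G/T"
                )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: REF and ALT must differ")

    @property
    def pos0(self) -> int:
        """0-based start of the REF span."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end of the REF span."""
        return self.pos - 1 + len(self.ref_allele)

    @property
    def variant_class(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNV"
        if len(self.alt_allele) > len(self.ref_allele):
            return "insertion"
        if len(self.ref_allele) > len(self.alt_allele):
            return "deletion"
        return "MNV"

    def swapped(self) -> "GenomicVariant":
        """The same site with REF and ALT exchanged (delta negates exactly)."""
        return GenomicVariant(
            chrom=self.chrom,
            pos=self.pos,
            ref_allele=self.alt_allele,
            alt_allele=self.ref_allele,
            variant_id=self.variant_id,
            is_dbsnp=self.is_dbsnp,
        )


@dataclass(frozen=True)
class DeltaScore:
    """Wild-type vs mutant motif score for one (variant, motif) pair."""

    motif_id: str
    variant_id: str
    wild_score: float
    mutant_score: float
    is_gain: bool

    @property
    def delta(self) -> float:
        return self.mutant_score - self.wild_score


def window_size_for_motif(motif_length: int) -> int:
    """Scan-window size in bp as a function of motif length (20 / 30 / 60)."""
    if motif_length < 1:
        raise ValueError("motif length must be positive")
    if motif_length <= 15:
        return 20
    if motif_length <= 25:
        return 30
    return 60


def extract_allele_windows(genome, variant: GenomicVariant, window: int):
    """Reference and mutant sequence windows centered on the variant's REF span.

    ``genome`` is any mapping of chromosome name to a sliceable sequence
    (e.g. a ``pyfaidx.Fasta``). Returns uppercase ``(ref_seq, mut_seq)``; the
    reference window has length ``window + len(ref_allele) - 1`` (left flank
    gets the smaller half), the mutant window differs by the indel length.
    Raises :class:`ReferenceMismatchError` if REF disagrees with the genome.
    """
    chrom_seq = genome[variant.chrom]
    chrom_len = len(chrom_seq)
    left = (window - 1) // 2
    right = window - 1 - left

    start = variant.pos0 - left
    end = variant.end0 + right
    if start < 0 or end > chrom_len:
        log.warning(
            "window for %s at %s:%d truncated at contig edge",
            variant.variant_id,
            variant.chrom,
            variant.pos,
        )
        start = max(start, 0)
        end = min(end, chrom_len)

    ref_seq = str(chrom_seq[start:end]).upper()
    ref_offset = variant.pos0 - start
    observed = ref_seq[ref_offset : ref_offset + len(variant.ref_allele)]
    if observed != variant.ref_allele:
        raise ReferenceMismatchError(
            f"variant {variant.variant_id} at {variant.chrom}:{variant.pos}: "
            f"REF {variant.ref_allele!r} but genome has {observed!r}"
        )
    mut_seq = (
        ref_seq[:ref_offset]
        + variant.alt_allele
        + ref_seq[ref_offset + len(variant.ref_allele) :]
    )
    return ref_seq, mut_seq


def call_gain(
    wild_score: float,
    mutant_score: float,
    min_mutant_score: float = DEFAULT_MIN_MUTANT_SCORE,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> bool:
    """Gain rule: the mutant score clears its threshold AND the delta clears its own.

    Both conditions are required: e.g. (wild 0.87, mutant 0.95) is not a gain
    because the delta 0.08 falls short of 0.1. Comparisons are inclusive with
    a 1e-9 tolerance so float rounding cannot flip a boundary case.
    """
    return (
        mutant_score >= min_mutant_score - THRESHOLD_EPS
        and (mutant_score - wild_score) >= min_delta - THRESHOLD_EPS
    )


def delta_score(
    pwm: PWM,
    bg: BackgroundModel,
    ref_seq: str,
    mut_seq: str,
    variant_id: str = ".",
    min_mutant_score: float = DEFAULT_MIN_MUTANT_SCORE,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> DeltaScore:
    """Score both alleles' windows and call a gain per the two thresholds."""
    wild = score_window(pwm, bg, ref_seq)
    mutant = score_window(pwm, bg, mut_seq)
    is_gain = call_gain(wild, mutant, min_mutant_score, min_delta)
    return DeltaScore(
        motif_id=pwm.motif_id,
        variant_id=variant_id,
        wild_score=wild,
        mutant_score=mutant,
        is_gain=is_gain,
    )


def score_variants_against_regulators(
    variants: Sequence[GenomicVariant],
    master_motifs: Iterable[PWM],
    genome,
    bg: BackgroundModel,
    min_mutant_score: float = DEFAULT_MIN_MUTANT_SCORE,
    min_delta: float = DEFAULT_MIN_DELTA,
    include_losses: bool = False,
) -> list:
    """All (variant, motif) gain calls for the master-regulator motif set.

    Returns ``(variant, DeltaScore)`` pairs with ``is_gain`` true, in
    deterministic (chrom, pos, motif_id) order. A variant may appear once per
    gained motif. With ``include_losses`` (off by default, mirroring the
    gain-of-function focus), strong losses (wild >= min_mutant_score and
    delta <= -min_delta) are returned as well, with ``is_gain`` false.
    """
    motifs = sorted(master_motifs, key=lambda p: p.motif_id)
    if not motifs:
        raise ValueError("master motif set is empty")

    results = []
    for variant in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref_allele, v.alt_allele)):
        for pwm in motifs:
            window = window_size_for_motif(pwm.length)
            window = max(window, pwm.length)  # never narrower than the motif
            ref_seq, mut_seq = extract_allele_windows(genome, variant, window)
            ds = delta_score(
                pwm,
                bg,
                ref_seq,
                mut_seq,
                variant_id=variant.variant_id,
                min_mutant_score=min_mutant_score,
                min_delta=min_delta,
            )
            if ds.is_gain:
                results.append((variant, ds))
            elif include_losses and call_gain(ds.mutant_score, ds.wild_score,
                                              min_mutant_score, min_delta):
                results.append((variant, ds))
    return results
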