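"""Self-consistent synthetic datasets with planted cis-gain-of-function events.

The generator fabricates every input the pipeline consumes — genome FASTA,
VCF, gene models, expression Z-scores, PWM collection, motif->TF annotations,
a motif-ranking database, relevant/driver gene lists, TADs, H3K27ac peaks,
het-SNP allele counts, and a dbSNP subset — around one or more *planted*
events: a variant engineered so that its mutant allele completes the
consensus of a chosen motif (scoring 1.0) while the reference allele carries
a broken site (scoring below 0.8). Everything else is drawn to be inert:
background variants are rejection-sampled until they gain no planted-TF
motif, non-signature genes sit below the over-expression threshold, and
non-planted motifs carry random gene rankings.

The emulated scenario mirrors a leukemia-style enhancer insertion a few kb
upstream of an over-expressed oncogene among dozens of bystander mutations,
so the end-to-end pipeline should recover exactly the planted candidates.

A seed fully determines every output file, byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .pwm import ALPHABET, PWM, BackgroundModel
from .variant_scoring import (
    GenomicVariant,
    delta_score,
    extract_allele_windows,
    window_size_for_motif,
)

log = logging.getLogger(__name__)

MAX_PLANT_ATTEMPTS = 1000


@dataclass(frozen=True)
class PlantedEvent:
    """One engineered cis-GoF event: variant class and distance upstream of the target TSS."""

    distance_to_tss: int = 7500
    variant_class: str = "insertion"  # "insertion" or "SNV"
    target_index: int | None = None  # index into the gene list; None = auto
    motif_index: int | None = None  # index into the motif list; None = event order


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset; the seed determines all randomness."""

    seed: int = 42
    sample_id: str = "SYNTH"
    n_chroms: int = 1
    chrom_length: int = 400_000
    gc_content: float = 0.41
    n_genes: int = 500
    n_motifs: int = 50
    motif_length_range: tuple = (8, 12)
    motif_dominant_prob: float = 0.97
    signature_size: int = 40
    planted: list = field(default_factory=lambda: [PlantedEvent()])
    background_variant_count: int = 67
    n_dbsnp_snps: int = 8
    tad_size: int = 100_000
    tad_pad: int = 2_000
    n_null_ase_genes: int = 20
    ase_truth: dict | None = None  # gene -> true major-allele fraction; None = targets at 0.8
    expression_signature_z: float = 2.0


class FixtureGenerationError(RuntimeError):
    """Planted-event verification failed within the attempt budget."""


def _random_dna(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _codes_to_str(codes) -> str:
    return "".join(ALPHABET[c] for c in codes)


def _make_motifs(rng, spec: FixtureSpec) -> list:
    motifs = []
    lo, hi = spec.motif_length_range
    rest = (1.0 - spec.motif_dominant_prob) / 3
    for i in range(spec.n_motifs):
        length = int(rng.integers(lo, hi + 1))
        dominant = rng.integers(0, 4, size=length)
        mat = np.full((length, 4), rest)
        mat[np.arange(length), dominant] = spec.motif_dominant_prob
        motifs.append(PWM(motif_id=f"M{i:03d}", matrix=mat))
    return motifs


def _snv_breakable_motif(rng, motif_id: str) -> PWM:
    """A motif whose information is concentrated in one column.

    A single-base change at that column swings the normalized score by well
    over the gain delta, so an SNV can both create the site (mutant 1.0) and
    leave the reference clearly below threshold. Uniformly peaked matrices
    spread information too thinly for one SNV to do that.
    """
    length = 8
    dominant = rng.integers(0, 4, size=length)
    mat = np.full((length, 4), 0.15)
    mat[np.arange(length), dominant] = 0.55
    key = length // 2
    mat[key] = 0.01
    mat[key, dominant[key]] = 0.97
    return PWM(motif_id=motif_id, matrix=mat)


def _estimate_bg(genome: dict) -> BackgroundModel:
    return BackgroundModel.from_sequences(genome.values())


class _Planted:
    """Bookkeeping for one realized planted event."""

    def __init__(self, event, motif, tf_gene, target_gene, variant):
        self.event = event
        self.motif = motif
        self.tf_gene = tf_gene
        self.target_gene = target_gene
        self.variant = variant


def _plant_event(rng, genome_codes, chrom, pos0_site, motif, variant_class, bg_fn):
    """Engineer the genome around ``pos0_site`` and return the planted variant.

    The full motif consensus appears only on the mutant allele; flanks are
    redrawn until the reference window scores < 0.8 and the gain thresholds
    are met.
    """
    consensus_codes = motif.matrix.argmax(axis=1)
    L = motif.length
    window = max(window_size_for_motif(L), L)
    flank = window  # redraw this much context on each side

    for attempt in range(MAX_PLANT_ATTEMPTS):
        if variant_class == "insertion":
            n_ins = 3 if L > 6 else 2
            m = int(rng.integers(2, L - n_ins - 1))
            broken = np.concatenate([consensus_codes[:m], consensus_codes[m + n_ins:]])
            site_start = pos0_site
            var_pos0 = site_start + m - 1
            ref_allele = ALPHABET[consensus_codes[m - 1]]
            alt_allele = ref_allele + _codes_to_str(consensus_codes[m : m + n_ins])
        elif variant_class == "SNV":
            j = int(np.argmax(motif.matrix.max(axis=1)))
            worst = int(motif.matrix[j].argmin())
            broken = consensus_codes.copy()
            broken[j] = worst
            site_start = pos0_site
            var_pos0 = site_start + j
            ref_allele = ALPHABET[worst]
            alt_allele = ALPHABET[consensus_codes[j]]
        else:
            raise ValueError(f"unsupported planted variant class: {variant_class}")

        codes = genome_codes[chrom]
        codes[site_start - flank : site_start] = _random_dna(rng, flank, 0.41)
        codes[site_start : site_start + len(broken)] = broken
        end = site_start + len(broken)
        codes[end : end + flank] = _random_dna(rng, flank, 0.41)

        variant = GenomicVariant(
            chrom=chrom,
            pos=var_pos0 + 1,
            ref_allele=ref_allele,
            alt_allele=alt_allele,
            variant_id=f"planted_{motif.motif_id}",
        )
        genome = {c: _codes_to_str(v) for c, v in genome_codes.items()}
        bg = bg_fn(genome)
        ref_seq, mut_seq = extract_allele_windows(genome, variant, window)
        ds = delta_score(motif, bg, ref_seq, mut_seq, variant_id=variant.variant_id)
        if ds.is_gain and ds.wild_score < 0.8:
            log.info(
                "planted %s after %d attempt(s): wild %.3f mutant %.3f",
                variant.variant_id, attempt + 1, ds.wild_score, ds.mutant_score,
            )
            return variant
    raise FixtureGenerationError(
        f"could not realize planted event for {motif.motif_id} "
        f"in {MAX_PLANT_ATTEMPTS} attempts"
    )


def generate_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Write a complete synthetic dataset to ``out_dir``; returns the truth record.

    The truth record (also saved as ``truth.json``) carries the planted
    variant ids, their motifs/TFs/targets, per-file bookkeeping counts, and
    rejection-sampling statistics, so tests can audit the pipeline funnel
    against the generator's own accounting.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    genome_codes = {c: _random_dna(rng, spec.chrom_length, spec.gc_content) for c in chroms}

    # genes: evenly spaced TSSs, round-robin over chromosomes
    spacing = spec.chrom_length // (spec.n_genes // spec.n_chroms + 1)
    genes = []
    for i in range(spec.n_genes):
        chrom = chroms[i % spec.n_chroms]
        slot = i // spec.n_chroms
        tss = (slot + 1) * spacing
        strand = "+" if (i % 2 == 0) else "-"
        genes.append((f"G{i:04d}", chrom, tss, strand))
    gene_names = [g[0] for g in genes]

    motifs = _make_motifs(rng, spec)
    # TF genes: the tail of the gene list, one per motif (kept off the relevant list
    # except for planted TFs, so only planted TFs can become master regulators)
    tf_gene_of_motif = {
        motifs[i].motif_id: gene_names[spec.n_genes - spec.n_motifs + i]
        for i in range(spec.n_motifs)
    }

    # resolve planted events
    planted: list = []
    used_targets: set = set()
    for idx, event in enumerate(spec.planted):
        midx = event.motif_index if event.motif_index is not None else idx
        if event.variant_class == "SNV":
            # swap in a motif a single base change can make or break
            motifs[midx] = _snv_breakable_motif(rng, motifs[midx].motif_id)
        motif = motifs[midx]
        tf_gene = tf_gene_of_motif[motif.motif_id]
        if event.target_index is not None:
            target = genes[event.target_index]
        else:
            frac = (idx + 1) / (len(spec.planted) + 1)
            target = genes[int(frac * (spec.n_genes - spec.n_motifs))]
        if target[0] in used_targets or target[0] == tf_gene:
            raise ValueError("planted events must use distinct, non-TF target genes")
        used_targets.add(target[0])
        planted.append(_Planted(event, motif, tf_gene, target, None))

    # plant each event into the genome with verification-in-the-loop
    for p in planted:
        _, chrom, tss, _ = p.target_gene
        site = tss - 1 - p.event.distance_to_tss
        if not (2 * 60 < site < spec.chrom_length - 2 * 60):
            raise ValueError("planted event does not fit within chromosome bounds")
        p.variant = _plant_event(
            rng, genome_codes, chrom, site, p.motif, p.event.variant_class, _estimate_bg
        )

    genome = {c: _codes_to_str(v) for c, v in genome_codes.items()}
    bg = _estimate_bg(genome)

    # re-verify all planted events against the final genome and background
    for p in planted:
        window = max(window_size_for_motif(p.motif.length), p.motif.length)
        ref_seq, mut_seq = extract_allele_windows(genome, p.variant, window)
        ds = delta_score(p.motif, bg, ref_seq, mut_seq)
        if not (ds.is_gain and ds.wild_score < 0.8):
            raise FixtureGenerationError("final verification of a planted event failed")

    # TAD around each planted pair; signature avoids genes inside planted TADs
    planted_tads = []
    for p in planted:
        lo = min(p.variant.pos0, p.target_gene[2] - 1) - spec.tad_pad
        hi = max(p.variant.end0, p.target_gene[2]) + spec.tad_pad
        planted_tads.append((p.variant.chrom, max(lo, 0), hi))

    def in_planted_tad(gene) -> bool:
        _, chrom, tss, _ = gene
        return any(c == chrom and lo <= tss - 1 < hi for c, lo, hi in planted_tads)

    # signature: planted targets + planted TFs + random filler genes
    signature = {p.target_gene[0] for p in planted} | {p.tf_gene for p in planted}
    tf_genes = set(tf_gene_of_motif.values())
    filler_pool = [
        g[0]
        for g in genes
        if g[0] not in signature and g[0] not in tf_genes and not in_planted_tad(g)
    ]
    n_filler = max(0, spec.signature_size - len(signature))
    signature |= set(rng.choice(filler_pool, size=n_filler, replace=False))

    # expression: signature at Z = 2, everything else truncated below 1
    expression = {}
    for name in gene_names:
        if name in signature:
            expression[name] = spec.expression_signature_z
        else:
            z = float(rng.normal())
            while z >= 1.0:
                z = float(rng.normal())
            expression[name] = round(z, 4)

    # relevance: planted TF + target, plus some signature filler; drivers: targets
    relevant = {p.tf_gene for p in planted} | {p.target_gene[0] for p in planted}
    extra_relevant = [g for g in sorted(signature) if g not in relevant and g not in tf_genes
                      and not in_planted_tad(genes[gene_names.index(g)])]
    relevant |= set(rng.choice(extra_relevant, size=min(15, len(extra_relevant)), replace=False))
    drivers = {p.target_gene[0] for p in planted}

    # ranking database: planted motifs concentrate the signature at the top
    sig_list = sorted(signature)
    ranks = np.empty((spec.n_motifs, spec.n_genes), dtype=int)
    planted_motif_ids = {p.motif.motif_id for p in planted}
    for i, motif in enumerate(motifs):
        if motif.motif_id in planted_motif_ids:
            row = np.empty(spec.n_genes, dtype=int)
            sig_idx = [gene_names.index(g) for g in sig_list]
            other_idx = [j for j in range(spec.n_genes) if gene_names[j] not in signature]
            row[sig_idx] = rng.permutation(len(sig_idx)) + 1
            row[other_idx] = rng.permutation(len(other_idx)) + len(sig_idx) + 1
            ranks[i] = row
        else:
            ranks[i] = rng.permutation(spec.n_genes) + 1

    # coding exons: short intervals downstream of every 10th non-planted gene TSS
    exons = []
    planted_spans = [(p.variant.chrom, p.variant.pos0 - 200, p.variant.end0 + 200) for p in planted]
    for g in genes[::10]:
        name, chrom, tss, _ = g
        start, end = tss + 99, tss + 250
        clash = any(c == chrom and start < hi and lo < end for c, lo, hi in planted_spans)
        if not clash and end < spec.chrom_length:
            exons.append((chrom, start, end))

    # background variants: rejection-sampled SNVs that gain no planted-TF motif
    def random_background_variant(vid: str):
        rejections = 0
        while True:
            chrom = chroms[int(rng.integers(0, spec.n_chroms))]
            pos0 = int(rng.integers(100, spec.chrom_length - 100))
            near_plant = any(
                c == chrom and lo - 100 <= pos0 < hi + 100 for c, lo, hi in planted_spans
            )
            in_exon = any(c == chrom and lo <= pos0 < hi for c, lo, hi in exons)
            if near_plant or in_exon or pos0 in used_positions.get(chrom, set()):
                rejections += 1
                continue
            ref = genome[chrom][pos0]
            alt = ALPHABET[int(rng.choice([b for b in range(4) if ALPHABET[b] != ref]))]
            variant = GenomicVariant(chrom, pos0 + 1, ref, alt, variant_id=vid)
            gained = False
            for p in planted:
                window = max(window_size_for_motif(p.motif.length), p.motif.length)
                r, m = extract_allele_windows(genome, variant, window)
                if delta_score(p.motif, bg, r, m).is_gain:
                    gained = True
                    break
            if gained:
                rejections += 1
                continue
            used_positions.setdefault(chrom, set()).add(pos0)
            return variant, rejections

    used_positions: dict = {}
    background: list = []
    total_rejections = 0
    for i in range(spec.background_variant_count):
        v, rej = random_background_variant(f"bg_{i:04d}")
        background.append(v)
        total_rejections += rej
    dbsnp_variants: list = []
    for i in range(spec.n_dbsnp_snps):
        v, rej = random_background_variant(f"snp_{i:04d}")
        dbsnp_variants.append(v)
        total_rejections += rej
    if total_rejections:
        log.info("background variant rejection-sampling: %d redraws", total_rejections)

    # TADs: planted TAD(s) + non-overlapping tiles, two TAD samples
    tad_rows = []
    for sample in ("tissueA", "cellB"):
        intervals = list(planted_tads)
        for chrom in chroms:
            blocked = sorted((lo, hi) for c, lo, hi in planted_tads if c == chrom)
            for pos in range(0, spec.chrom_length, spec.tad_size):
                tile = (pos, min(pos + spec.tad_size, spec.chrom_length))
                if any(tile[0] < hi and lo < tile[1] for lo, hi in blocked):
                    continue
                intervals.append((chrom, tile[0], tile[1]))
        for chrom, lo, hi in sorted(intervals):
            tad_rows.append((chrom, lo, hi, sample))

    # H3K27ac peaks over each planted variant + inert decoys
    peak_rows = [
        (p.variant.chrom, max(p.variant.pos0 - 250, 0), p.variant.end0 + 250)
        for p in planted
    ]
    for _ in range(10):
        chrom = chroms[int(rng.integers(0, spec.n_chroms))]
        start = int(rng.integers(0, spec.chrom_length - 600))
        peak_rows.append((chrom, start, start + 500))
    peak_rows = sorted(set(peak_rows))

    # allele counts realizing the per-gene true major-allele fractions
    ase_truth = dict(spec.ase_truth) if spec.ase_truth is not None else {
        p.target_gene[0]: 0.8 for p in planted
    }
    null_pool = [g for g in sorted(signature) if g not in ase_truth]
    for g in null_pool[: spec.n_null_ase_genes]:
        ase_truth[g] = 0.5
    allele_rows = []
    for gene_name in sorted(ase_truth):
        maf = ase_truth[gene_name]
        n_snps = 5 if maf > 0.5 else 3
        for s in range(n_snps):
            n = 40
            major = int(rng.binomial(n, maf))
            # randomize which allele is major so ref/alt labels are unbiased
            if rng.random() < 0.5:
                ref_reads, alt_reads = major, n - major
            else:
                ref_reads, alt_reads = n - major, major
            allele_rows.append((gene_name, f"{gene_name}_snp{s}", ref_reads, alt_reads))

    # ----- write everything -----
    mio.write_fasta(out / "genome.fa", genome)
    all_variants = sorted(
        [(p.variant, {"DP": 60, "MC": 30, "VAF": 0.5}) for p in planted]
        + [(v, {"DP": 60, "MC": 30, "VAF": 0.5}) for v in background]
        + [(v, {"DP": 60, "MC": 30, "VAF": 0.5}) for v in dbsnp_variants],
        key=lambda t: (t[0].chrom, t[0].pos, t[0].alt_allele),
    )
    mio.write_vcf(
        out / "variants.vcf",
        [(v.chrom, v.pos, v.variant_id, v.ref_allele, v.alt_allele, info)
         for v, info in all_variants],
        contigs={c: spec.chrom_length for c in chroms},
    )
    mio.write_tsv(out / "genes.tsv", ["gene", "chrom", "tss", "strand"], genes)
    mio.write_tsv(
        out / "expression.tsv", ["gene", "z"],
        [(g, expression[g]) for g in gene_names],
    )
    mio.write_motifs_cb(out / "motifs.cb", motifs)
    mio.write_tsv(
        out / "motif2tf.tsv", ["motif_id", "tf_symbol"],
        [(m.motif_id, tf_gene_of_motif[m.motif_id]) for m in motifs],
    )
    header = ["motif_id"] + gene_names
    mio.write_tsv(
        out / "rankings.tsv", header,
        [[motifs[i].motif_id] + list(ranks[i]) for i in range(spec.n_motifs)],
    )
    (out / "relevant_genes.txt").write_text("".join(f"{g}\n" for g in sorted(relevant)))
    (out / "driver_genes.txt").write_text("".join(f"{g}\n" for g in sorted(drivers)))
    mio.write_bed(out / "tads.bed", tad_rows)
    mio.write_bed(out / "peaks_h3k27ac.bed", peak_rows)
    mio.write_bed(out / "coding_exons.bed", sorted(exons))
    mio.write_tsv(
        out / "dbsnp.tsv", ["chrom", "pos", "ref", "alt"],
        [(v.chrom, v.pos, v.ref_allele, v.alt_allele) for v in dbsnp_variants],
    )
    mio.write_tsv(
        out / "allele_counts.tsv", ["gene", "snp_id", "ref_reads", "alt_reads"],
        allele_rows,
    )

    config = {
        "sample_id": spec.sample_id,
        "seed": int(spec.seed),
        "paths": {
            "genome": "genome.fa",
            "variants": "variants.vcf",
            "genes": "genes.tsv",
            "expression": "expression.tsv",
            "motifs": "motifs.cb",
            "motif2tf": "motif2tf.tsv",
            "rankings": "rankings.tsv",
            "relevant_genes": "relevant_genes.txt",
            "driver_genes": "driver_genes.txt",
            "tads": "tads.bed",
            "coding_exons": "coding_exons.bed",
            "allele_counts": "allele_counts.tsv",
            "dbsnp": "dbsnp.tsv",
        },
        "peaks": {"H3K27ac": "peaks_h3k27ac.bed"},
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    truth = {
        "seed": int(spec.seed),
        "sample_id": spec.sample_id,
        "planted": [
            {
                "variant_id": p.variant.variant_id,
                "chrom": p.variant.chrom,
                "pos": p.variant.pos,
                "ref": p.variant.ref_allele,
                "alt": p.variant.alt_allele,
                "motif_id": p.motif.motif_id,
                "tf": p.tf_gene,
                "target_gene": p.target_gene[0],
                "distance_to_tss": p.event.distance_to_tss,
                "variant_class": p.event.variant_class,
            }
            for p in planted
        ],
        "n_variants_total": len(all_variants),
        "n_mutation_track": len(planted) + len(background),
        "n_snp_track": len(dbsnp_variants),
        "n_signature_genes": len(signature),
        "n_relevant_genes": len(relevant),
        "background_rejections": total_rejections,
        "ase_truth": {g: ase_truth[g] for g in sorted(ase_truth)},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
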