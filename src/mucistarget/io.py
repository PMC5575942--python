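"""Readers and writers for every external format, with centralized coordinate handling.

Conventions: VCF positions are 1-based (kept on ``GenomicVariant.pos``); all
interval formats (BED: exons, TADs, peaks) are 0-based half-open and stay
that way internally. Chromosome names are harmonized to the genome FASTA's
convention ("chr1" vs "1") at load time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta

from .annotation import GeneModel, TADSet, VariantCallRecord
from .evidence import PeakSet
from .pwm import PWM, pwm_from_counts
from .regulon import MotifRankingDatabase
from .variant_scoring import GenomicVariant

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """A malformed input file; the message names file, line, and rule."""


# ---------------------------------------------------------------------------
# motif collections


def read_motifs(path, motif2tf: dict | None = None) -> list:
    """Read a PWM collection in Cluster-Buster or JASPAR text format.

    Cluster-Buster: ``>motif_id`` then L rows of 4 numbers (A C G T columns).
    JASPAR: ``>motif_id`` then 4 letter-prefixed rows ``A [ 1 2 ... ]``.
    Numbers may be counts or probabilities; rows summing to 1 (+-0.01) are
    treated as probabilities (no pseudocount renormalization applied).
    """
    path = Path(path)
    motif2tf = motif2tf or {}
    blocks: list = []
    current_id = None
    current_lines: list = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current_id is not None:
                    blocks.append((current_id, current_lines))
                current_id = line[1:].split()[0]
                current_lines = []
            else:
                if current_id is None:
                    raise ValidationError(f"{path}: data before first '>' header")
                current_lines.append(line)
    if current_id is not None:
        blocks.append((current_id, current_lines))

    motifs = []
    for motif_id, lines in blocks:
        matrix = _parse_motif_block(path, motif_id, lines)
        tfs = frozenset(motif2tf.get(motif_id, ()))
        row_sums = matrix.sum(axis=1)
        if np.all(np.abs(row_sums - 1.0) <= 0.01):
            probs = matrix / row_sums[:, None]
            motifs.append(PWM(motif_id=motif_id, matrix=probs, tf_annotations=tfs))
        else:
            motifs.append(
                pwm_from_counts(matrix, motif_id=motif_id, tf_annotations=tfs)
            )
    return motifs


def _parse_motif_block(path, motif_id, lines) -> np.ndarray:
    jaspar = [ln for ln in lines if ln[0] in "ACGT" and not ln[0].isdigit()]
    if len(jaspar) == len(lines) == 4:
        rows = {}
        for ln in lines:
            base = ln[0]
            nums = ln[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(x) for x in nums]
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1 or set(rows) != set("ACGT"):
            raise ValidationError(f"{path}: motif {motif_id}: malformed JASPAR block")
        return np.array([rows[b] for b in "ACGT"]).T
    matrix = []
    for ln in lines:
        parts = ln.split()
        if len(parts) != 4:
            raise ValidationError(
                f"{path}: motif {motif_id}: expected 4 columns, got {len(parts)}"
            )
        matrix.append([float(x) for x in parts])
    return np.array(matrix)


def read_motif2tf(path) -> dict:
    """Motif -> set-of-TF annotation table (TSV: motif_id, tf_symbol)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "motif_id" not in cols or "tf_symbol" not in cols:
        raise ValidationError(f"{path}: need columns motif_id and tf_symbol")
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(str(row[cols["motif_id"]]), set()).add(
            str(row[cols["tf_symbol"]]).upper()
        )
    return out


# ---------------------------------------------------------------------------
# tables


def read_gene_models(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "chrom", "tss", "strand"}
    if not required.issubset({c.lower() for c in df.columns}):
        raise ValidationError(f"{path}: need columns gene, chrom, tss, strand")
    df.columns = [c.lower() for c in df.columns]
    return [
        GeneModel(
            gene_symbol=str(r.gene).upper(),
            chrom=str(r.chrom),
            tss=int(r.tss),
            strand=str(r.strand),
        )
        for r in df.itertuples()
    ]


def read_expression(path) -> dict:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    if "gene" not in df.columns or "z" not in df.columns:
        raise ValidationError(f"{path}: need columns gene, z")
    return {str(r.gene).upper(): float(r.z) for r in df.itertuples()}


def read_gene_list(path) -> frozenset:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.upper())
    return frozenset(out)


def read_rankings(path) -> MotifRankingDatabase:
    """Motif-ranking TSV: first column motif_id, header of gene symbols, integer ranks."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(int)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-integer rank value ({exc})") from exc
    try:
        return MotifRankingDatabase(df)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_allele_counts(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    required = {"gene", "snp_id", "ref_reads", "alt_reads"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: need columns gene, snp_id, ref_reads, alt_reads")
    return [
        (str(r.gene).upper(), str(r.snp_id), int(r.ref_reads), int(r.alt_reads))
        for r in df.itertuples()
    ]


def read_dbsnp(path) -> frozenset:
    """dbSNP subset as TSV (chrom, pos, ref, alt) or VCF; keys are allele-aware."""
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        out = set()
        for rec in VCF(str(path)):
            for alt in rec.ALT:
                out.add((rec.CHROM, rec.POS, rec.REF, alt))
        return frozenset(out)
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: need columns chrom, pos, ref, alt")
    return frozenset(
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)) for r in df.itertuples()
    )


# ---------------------------------------------------------------------------
# BED


def read_bed(path, min_fields: int = 3) -> list:
    """BED rows as (chrom, start, end, extra...) tuples; validates start < end."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_fields:
                raise ValidationError(
                    f"{path}:{lineno}: expected >= {min_fields} fields"
                )
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            rows.append((chrom, start, end, *parts[3:]))
    return rows


def read_tads(path) -> list:
    """TAD BED with sample_id in column 4; one TADSet per sample."""
    by_sample: dict = {}
    for row in read_bed(path, min_fields=4):
        chrom, start, end, sample_id = row[0], row[1], row[2], row[3]
        by_sample.setdefault(sample_id, []).append((chrom, start, end))
    return [TADSet(sample_id, ivs) for sample_id, ivs in sorted(by_sample.items())]


def read_peaks(path, sample_id: str, mark: str, merge_gap: int | None = 350) -> PeakSet:
    intervals = [(r[0], r[1], r[2]) for r in read_bed(path)]
    return PeakSet(sample_id=sample_id, intervals=intervals, mark=mark, merge_gap=merge_gap)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path) -> list:
    """Variant call records from a VCF; multi-allelic records are split per ALT.

    Depth / alt-supporting coverage / VAF are taken from INFO fields DP, MC,
    and VAF when present (absent fields default to depth 0 semantics being
    skipped: depth=None records become records with vaf=None etc.).
    """
    records = []
    for rec in VCF(str(path)):
        depth = rec.INFO.get("DP")
        mutcov = rec.INFO.get("MC")
        vaf = rec.INFO.get("VAF")
        for alt in rec.ALT:
            ref, a, pos = _normalize_alleles(rec.REF, alt, rec.POS)
            variant = GenomicVariant(
                chrom=rec.CHROM,
                pos=pos,
                ref_allele=ref,
                alt_allele=a,
                variant_id=rec.ID or f"{rec.CHROM}:{pos}:{ref}>{a}",
            )
            records.append(
                VariantCallRecord(
                    variant=variant,
                    depth=int(depth) if depth is not None else 0,
                    mutation_coverage=int(mutcov) if mutcov is not None else 0,
                    vaf=float(vaf) if vaf is not None else None,
                )
            )
    return records


def _normalize_alleles(ref: str, alt: str, pos: int):
    """Trim the shared suffix/prefix that VCF multi-allelic splitting can leave."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return ref, alt, pos


# ---------------------------------------------------------------------------
# chromosome-name harmonization


def harmonize_chroms(names, genome_names) -> dict:
    """Map input chromosome names onto the genome FASTA's naming convention."""
    genome_set = set(genome_names)
    mapping = {}
    warned = False
    for name in names:
        if name in genome_set:
            mapping[name] = name
        elif name.startswith("chr") and name[3:] in genome_set:
            mapping[name] = name[3:]
            warned = True
        elif "chr" + name in genome_set:
            mapping[name] = "chr" + name
            warned = True
        else:
            mapping[name] = name
    if warned:
        log.warning("chromosome names harmonized to the genome FASTA convention")
    return mapping


# ---------------------------------------------------------------------------
# Dataset


@dataclass
class Dataset:
    """All validated inputs of one sample run."""

    sample_id: str
    genome: Fasta
    variant_records: list
    genes: list
    expression: dict
    motifs: list
    motif2tf: dict
    rankings: MotifRankingDatabase
    relevant_genes: frozenset
    driver_genes: frozenset
    tads: list = field(default_factory=list)
    peaks: list = field(default_factory=list)
    allele_counts: list = field(default_factory=list)
    dbsnp: frozenset = field(default_factory=frozenset)
    coding_exons: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def load_dataset(config) -> Dataset:
    """Load and validate every input named in a :class:`~mucistarget.pipeline.RunConfig`.

    Chromosome names in variants, genes, TADs, peaks, and exons are mapped to
    the genome FASTA's convention; the REF allele of up to 100 variants is
    spot-checked against the genome (hard error on mismatch).
    """
    paths = config.paths
    genome = Fasta(str(paths["genome"]), sequence_always_upper=True)
    genome_names = list(genome.keys())

    motif2tf = read_motif2tf(paths["motif2tf"])
    motifs = read_motifs(paths["motifs"], motif2tf=motif2tf)
    records = read_vcf(paths["variants"])
    genes = read_gene_models(paths["genes"])

    chrom_map = harmonize_chroms(
        {r.variant.chrom for r in records}
        | {g.chrom for g in genes},
        genome_names,
    )
    records = [
        VariantCallRecord(
            variant=GenomicVariant(
                chrom=chrom_map[r.variant.chrom],
                pos=r.variant.pos,
                ref_allele=r.variant.ref_allele,
                alt_allele=r.variant.alt_allele,
                variant_id=r.variant.variant_id,
                is_dbsnp=r.variant.is_dbsnp,
            ),
            depth=r.depth,
            mutation_coverage=r.mutation_coverage,
            vaf=r.vaf,
        )
        if chrom_map[r.variant.chrom] != r.variant.chrom
        else r
        for r in records
    ]
    genes = [
        GeneModel(g.gene_symbol, chrom_map[g.chrom], g.tss, g.strand)
        if chrom_map[g.chrom] != g.chrom
        else g
        for g in genes
    ]

    # REF spot-check on a deterministic sample of variants
    for rec in records[:100]:
        v = rec.variant
        if v.chrom not in genome:
            raise ValidationError(f"variant {v.variant_id}: unknown chromosome {v.chrom}")
        observed = str(genome[v.chrom][v.pos0 : v.end0]).upper()
        if observed != v.ref_allele:
            raise ValidationError(
                f"variant {v.variant_id} at {v.chrom}:{v.pos}: REF "
                f"{v.ref_allele!r} does not match genome {observed!r}"
            )

    def _remap_bed(rows):
        m = harmonize_chroms({r[0] for r in rows}, genome_names)
        return [(m[r[0]], *r[1:]) for r in rows]

    tads = []
    if paths.get("tads"):
        tads = [
            TADSet(ts.sample_id, [
                (c, iv.begin, iv.end) for c, tree in ts.trees.items() for iv in sorted(tree)
            ])
            for ts in read_tads(paths["tads"])
        ]
    peaks = []
    for mark, peak_path in sorted((config.peak_paths or {}).items()):
        rows = _remap_bed(read_bed(peak_path))
        peaks.append(
            PeakSet(
                sample_id=config.sample_id,
                intervals=[(r[0], r[1], r[2]) for r in rows],
                mark=mark,
                merge_gap=config.peak_merge_gap,
            )
        )
    coding_exons = []
    if paths.get("coding_exons"):
        coding_exons = [
            (r[0], r[1], r[2]) for r in _remap_bed(read_bed(paths["coding_exons"]))
        ]

    dataset = Dataset(
        sample_id=config.sample_id,
        genome=genome,
        variant_records=records,
        genes=genes,
        expression=read_expression(paths["expression"]),
        motifs=motifs,
        motif2tf=motif2tf,
        rankings=read_rankings(paths["rankings"]),
        relevant_genes=read_gene_list(paths["relevant_genes"]),
        driver_genes=read_gene_list(paths["driver_genes"]),
        tads=tads,
        peaks=peaks,
        allele_counts=read_allele_counts(paths["allele_counts"])
        if paths.get("allele_counts")
        else [],
        dbsnp=read_dbsnp(paths["dbsnp"]) if paths.get("dbsnp") else frozenset(),
        coding_exons=coding_exons,
        provenance={
            "sample_id": config.sample_id,
            "files": {
                key: {"path": str(p), "sha256_16": _checksum(p)}
                for key, p in sorted(paths.items())
                if p and Path(p).is_file()
            },
        },
    )
    return dataset


# ---------------------------------------------------------------------------
# output


def _fmt(x) -> str:
    if isinstance(x, float):
        return format(x, ".6g")
    return str(x)


CANDIDATE_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "variant_id", "variant_class",
    "is_dbsnp", "motif_id", "tf", "target_gene", "distance", "wild_score",
    "mutant_score", "delta", "tad_samples", "in_peak", "peak_marks", "is_ase",
]


def write_candidates(candidates, tsv_path, json_path=None):
    """Write candidate records as a TSV and the gained-edge network as JSON.

    ``candidates`` are dicts with :data:`CANDIDATE_COLUMNS` keys. Rows are
    sorted by (sample, chrom, pos, motif_id); floats use 6 significant digits.
    """
    rows = sorted(
        candidates,
        key=lambda c: (c["sample"], c["chrom"], c["pos"], c["motif_id"], c["target_gene"]),
    )
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in rows:
            fh.write("\t".join(_fmt(c[col]) for col in CANDIDATE_COLUMNS) + "\n")
    if json_path is not None:
        write_network(rows, json_path)


def write_network(candidates, json_path, inferred_edges=(), node_z: dict | None = None):
    """Gene-regulatory-network JSON: TF and target nodes, inferred + gained edges."""
    node_z = node_z or {}
    nodes: dict = {}
    edges = []
    for tf, target in inferred_edges:
        nodes.setdefault(tf, "TF")
        nodes.setdefault(target, "target")
        edges.append({"source": tf, "target": target, "kind": "inferred",
                      "motif": None, "delta": None})
    for c in candidates:
        nodes[c["tf"]] = "TF"
        nodes.setdefault(c["target_gene"], "target")
        edges.append(
            {
                "source": c["tf"],
                "target": c["target_gene"],
                "kind": "gained",
                "motif": c["motif_id"],
                "delta": round(float(c["delta"]), 6),
            }
        )
    payload = {
        "nodes": [
            {"id": n, "role": role, "z": node_z.get(n)}
            for n, role in sorted(nodes.items())
        ],
        "edges": sorted(
            edges, key=lambda e: (e["kind"], e["source"], e["target"], str(e["motif"]))
        ),
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_candidates(tsv_path) -> list:
    """Round-trip reader for :func:`write_candidates` output."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str, "tad_samples": str, "peak_marks": str})
    df = df.fillna({"tad_samples": "", "peak_marks": ""})
    return df.to_dict(orient="records")


# ---------------------------------------------------------------------------
# plain-text writers (used by the synthetic-data generator)


def write_fasta(path, sequences: dict, width: int = 60):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf(path, rows, contigs: dict):
    """Minimal VCF 4.2 writer: rows of (chrom, pos, vid, ref, alt, info_dict)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=MC,Number=1,Type=Integer,Description="Alt-supporting reads">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, vid, ref, alt, info in rows:
            info_str = ";".join(f"{k}={_fmt(v)}" for k, v in info.items()) or "."
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info_str}\n")


def write_bed(path, rows):
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def write_motifs_cb(path, motifs):
    """Cluster-Buster-format PWM writer (probability rows, 6 decimals)."""
    with open(path, "w") as fh:
        for pwm in motifs:
            fh.write(f">{pwm.motif_id}\n")
            for row in pwm.matrix:
                fh.write("\t".join(format(x, ".6f") for x in row) + "\n")
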