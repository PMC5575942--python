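"""End-to-end orchestration: signature -> master regulators -> gain scoring ->
target filters -> TAD filter -> evidence layers, with a per-stage funnel log.

The pipeline consumes one sample's matched genome/variants/expression (plus
optional TADs, peaks, allele counts) and emits candidate cis-GoF records:
variant x motif x target-gene rows where the mutant allele gains a motif of a
sample-specific master regulator near an over-expressed, cancer-relevant
target. Candidates from several samples can be aggregated into a recurrence
report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import annotation as ann
from . import evidence as ev
from . import io as mio
from . import regulon as reg
from .pwm import BackgroundModel
from .variant_scoring import score_variants_against_regulators

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds, and flags of one sample run; defaults follow the method."""

    sample_id: str
    paths: dict
    peak_paths: dict = field(default_factory=dict)
    min_mutant_score: float = 0.90
    min_delta: float = 0.1
    nes_threshold: float = 3.0
    roc_fraction: float = 0.03
    rank_threshold: int = 5000
    min_expression_z: float = 1.0
    max_tss_distance: int = 1_000_000
    min_depth: int = 10
    min_mutation_coverage: int = 5
    min_vaf: float = 0.20
    ase_alpha: float = 0.05
    min_ase_maf: float = 0.6
    min_reads_per_allele: int = 5
    min_het_vaf: float = 0.10
    peak_merge_gap: int = 350
    tad_filter: bool = True
    snp_track: bool = True
    loss_scoring: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.min_mutant_score <= 1 and 0 <= self.min_delta <= 2):
            raise ValueError("gain-calling thresholds out of range")
        if not (0 < self.roc_fraction < 1):
            raise ValueError("roc_fraction must be in (0, 1)")
        if self.max_tss_distance < 0 or self.rank_threshold < 0:
            raise ValueError("distances/thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        paths = {
            k: str(base / v) if v else None for k, v in (raw.get("paths") or {}).items()
        }
        peak_paths = {k: str(base / v) for k, v in (raw.get("peaks") or {}).items()}
        kwargs = {
            k: v
            for k, v in raw.items()
            if k not in {"paths", "peaks"}
        }
        return cls(paths=paths, peak_paths=peak_paths, **kwargs)

    def to_yaml(self, path, relative_to=None) -> None:
        raw = asdict(self)
        if relative_to is not None:
            rel = Path(relative_to)
            raw["paths"] = {
                k: str(Path(v).resolve().relative_to(rel.resolve())) if v else None
                for k, v in self.paths.items()
            }
            raw["peaks"] = {
                k: str(Path(v).resolve().relative_to(rel.resolve()))
                for k, v in self.peak_paths.items()
            }
        else:
            raw["paths"] = dict(self.paths)
            raw["peaks"] = dict(self.peak_paths)
        raw.pop("peak_paths")
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class SampleResult:
    sample_id: str
    candidates: list
    snp_candidates: list
    master_regulators: list
    enriched_motifs: list
    funnel: list  # (stage, count) in execution order
    enrichment_tests: dict  # mark -> {track -> {k, K, m, N, p}}
    ase_results: dict


def _funnel_append(funnel: list, stage: str, count: int, not_more_than: int | None = None) -> None:
    """Record a funnel stage; a filter stage must not grow its input."""
    if not_more_than is not None and count > not_more_than:
        raise AssertionError(
            f"funnel grew at stage {stage}: {count} > {not_more_than}"
        )
    funnel.append((stage, count))
    log.info("funnel %s: %d", stage, count)


def run_sample(config: RunConfig, out_dir=None, dataset=None) -> SampleResult:
    """Execute the full pipeline for one sample.

    When ``out_dir`` is given, writes candidates.tsv, network.json,
    evidence.tsv, funnel.jsonl, and run_config.yaml there. ``dataset`` may be
    supplied directly (already loaded) to skip file loading.
    """
    if dataset is None:
        dataset = mio.load_dataset(config)
    funnel: list = []

    # 1. signature from expression
    signature_genes = {
        g for g, z in dataset.expression.items() if z > config.min_expression_z
    }
    signature = reg.GeneSignature(sample_id=config.sample_id, genes=frozenset(signature_genes))
    funnel.append(("signature_genes", len(signature_genes)))

    # 2. motif enrichment and master regulators
    enriched = reg.enriched_motifs(
        dataset.rankings,
        signature,
        nes_threshold=config.nes_threshold,
        roc_fraction=config.roc_fraction,
        rank_threshold=config.rank_threshold,
        motif2tf=dataset.motif2tf,
    )
    funnel.append(("enriched_motifs", len(enriched)))
    masters = reg.master_regulators(
        enriched,
        dataset.motif2tf,
        dataset.expression,
        dataset.relevant_genes | dataset.driver_genes,
        min_expression_z=config.min_expression_z,
    )
    funnel.append(("master_regulators", len(masters)))

    empty = SampleResult(
        sample_id=config.sample_id,
        candidates=[],
        snp_candidates=[],
        master_regulators=masters,
        enriched_motifs=enriched,
        funnel=funnel,
        enrichment_tests={},
        ase_results={},
    )
    if not masters:
        log.info("no master regulators found for %s; finishing with empty candidates",
                 config.sample_id)
        if out_dir is not None:
            _write_outputs(config, empty, out_dir)
        return empty

    master_motif_ids = set().union(*(m.motifs for m in masters))
    master_motifs = [p for p in dataset.motifs if p.motif_id in master_motif_ids]
    motif_tf = {
        p.motif_id: sorted(p.tf_annotations & {m.tf_symbol for m in masters})
        for p in master_motifs
    }

    # 3. variant-level filters
    records = dataset.variant_records
    funnel.append(("variants:raw", len(records)))
    records = ann.filter_variant_calls(
        records,
        min_depth=config.min_depth,
        min_mutation_coverage=config.min_mutation_coverage,
        min_vaf=config.min_vaf,
    )
    _funnel_append(funnel, "variants:call_filters", len(records),
                   not_more_than=funnel[-1][1])
    variants = [r.variant for r in records]
    variants = ann.exclude_coding(variants, dataset.coding_exons)
    _funnel_append(funnel, "variants:non_coding", len(variants),
                   not_more_than=funnel[-1][1])
    variants = ann.flag_dbsnp(variants, dataset.dbsnp)
    mutation_track = [v for v in variants if not v.is_dbsnp]
    snp_track = [v for v in variants if v.is_dbsnp] if config.snp_track else []
    funnel.append(("variants:mutation_track", len(mutation_track)))
    funnel.append(("variants:snp_track", len(snp_track)))

    bg = BackgroundModel.from_sequences(
        str(dataset.genome[c][:]) for c in dataset.genome.keys()
    )

    gene_index = {g.gene_symbol: g for g in dataset.genes}
    ase = ev.ase_by_gene(
        dataset.allele_counts,
        rng=np.random.default_rng(config.seed + 1),
        alpha=config.ase_alpha,
        min_maf=config.min_ase_maf,
        min_reads_per_allele=config.min_reads_per_allele,
        min_vaf=config.min_het_vaf,
    ) if dataset.allele_counts else {}

    def candidates_for(track, track_name):
        # 4. variant-to-gene assignment and target filters
        pairs = ann.assign_to_genes(track, dataset.genes, config.max_tss_distance)
        funnel.append((f"pairs[{track_name}]:within_1mb", len(pairs)))
        pairs = ann.filter_target_genes(
            pairs,
            dataset.expression,
            dataset.relevant_genes,
            dataset.driver_genes,
            min_expression_z=config.min_expression_z,
        )
        _funnel_append(funnel, f"pairs[{track_name}]:target_filters", len(pairs),
                       not_more_than=funnel[-1][1])
        scorable = sorted(
            {v.variant_id: v for v, _, _ in pairs}.values(),
            key=lambda v: (v.chrom, v.pos, v.alt_allele),
        )
        funnel.append((f"variants[{track_name}]:near_targets", len(scorable)))

        # 5. motif-gain scoring against master-regulator motifs
        gains = score_variants_against_regulators(
            scorable,
            master_motifs,
            dataset.genome,
            bg,
            min_mutant_score=config.min_mutant_score,
            min_delta=config.min_delta,
            include_losses=config.loss_scoring,
        )
        gains = [(v, d) for v, d in gains if d.is_gain]
        funnel.append((f"gains[{track_name}]", len(gains)))

        pair_by_variant: dict = {}
        for v, g, d in pairs:
            pair_by_variant.setdefault(v.variant_id, []).append((g, d))

        rows = []
        for variant, ds in gains:
            for gene, dist in pair_by_variant[variant.variant_id]:
                tad_samples = ann.annotate_tad(variant, gene, dataset.tads)
                if config.tad_filter and dataset.tads and not tad_samples:
                    continue
                for tf in motif_tf[ds.motif_id] or [""]:
                    rows.append(
                        {
                            "sample": config.sample_id,
                            "chrom": variant.chrom,
                            "pos": variant.pos,
                            "ref": variant.ref_allele,
                            "alt": variant.alt_allele,
                            "variant_id": variant.variant_id,
                            "variant_class": variant.variant_class,
                            "is_dbsnp": variant.is_dbsnp,
                            "motif_id": ds.motif_id,
                            "tf": tf,
                            "target_gene": gene.gene_symbol,
                            "distance": dist,
                            "wild_score": ds.wild_score,
                            "mutant_score": ds.mutant_score,
                            "delta": ds.delta,
                            "tad_samples": ",".join(sorted(tad_samples)),
                            "in_peak": False,
                            "peak_marks": "",
                            "is_ase": False,
                        }
                    )
        funnel.append((f"candidates[{track_name}]:tad_filtered", len(rows)))

        # 6. evidence layers
        if dataset.peaks:
            cand_variants = {r["variant_id"] for r in rows}
            flags = ev.overlap_peaks(
                [v for v in scorable if v.variant_id in cand_variants], dataset.peaks
            )
            for r in rows:
                marks = [m for m, hit in flags.get(r["variant_id"], {}).items() if hit]
                r["in_peak"] = bool(marks)
                r["peak_marks"] = ",".join(sorted(marks))
        for r in rows:
            res = ase.get(r["target_gene"])
            r["is_ase"] = bool(res.is_ase) if res is not None else False

        enrich = {}
        if dataset.peaks:
            universe = scorable
            for ps in dataset.peaks:
                n_univ_in = sum(ps.overlaps(v.chrom, v.pos0, v.end0) for v in universe)
                cand_ids = sorted({r["variant_id"] for r in rows})
                k = sum(
                    ps.overlaps(v.chrom, v.pos0, v.end0)
                    for v in universe
                    if v.variant_id in set(cand_ids)
                )
                K, N = len(cand_ids), len(universe)
                p = ev.peak_enrichment(k, K, n_univ_in, N) if N else 1.0
                enrich[ps.mark] = {"k": k, "K": K, "m": n_univ_in, "N": N, "p": p}
        return rows, enrich

    candidates, mut_enrich = candidates_for(mutation_track, "mut")
    snp_candidates, snp_enrich = (
        candidates_for(snp_track, "snp") if snp_track else ([], {})
    )

    result = SampleResult(
        sample_id=config.sample_id,
        candidates=candidates,
        snp_candidates=snp_candidates,
        master_regulators=masters,
        enriched_motifs=enriched,
        funnel=funnel,
        enrichment_tests={"mut": mut_enrich, "snp": snp_enrich},
        ase_results=ase,
    )
    if out_dir is not None:
        _write_outputs(config, result, out_dir)
    return result


def _write_outputs(config: RunConfig, result: SampleResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_rows = result.candidates + result.snp_candidates
    inferred = sorted(
        {
            (tf, gene)
            for em in result.enriched_motifs
            for tf in em.tfs
            for gene in sorted(em.leading_edge_genes)
            if any(tf == m.tf_symbol for m in result.master_regulators)
        }
    )
    mio.write_candidates(all_rows, out / "candidates.tsv")
    mio.write_network(
        sorted(all_rows, key=lambda c: (c["sample"], c["chrom"], c["pos"], c["motif_id"])),
        out / "network.json",
        inferred_edges=inferred,
    )
    mio.write_tsv(
        out / "evidence.tsv",
        ["track", "mark", "k", "K", "m", "N", "p"],
        [
            (track, mark, d["k"], d["K"], d["m"], d["N"], d["p"])
            for track, marks in sorted(result.enrichment_tests.items())
            for mark, d in sorted(marks.items())
        ],
    )
    mio.write_tsv(
        out / "ase.tsv",
        ["gene", "maf", "p", "padj", "is_ase", "n_snps", "total_reads"],
        [
            (r.gene_symbol, r.maf_estimate, r.p_value, r.adjusted_p,
             r.is_ase, r.n_snps, r.total_reads)
            for r in sorted(result.ase_results.values(), key=lambda r: r.gene_symbol)
        ],
    )
    with open(out / "funnel.jsonl", "w") as fh:
        for stage, count in result.funnel:
            fh.write(json.dumps({"stage": stage, "count": count}) + "\n")
    config.to_yaml(out / "run_config.yaml")


def recurrence_report(per_sample_candidates: dict) -> dict:
    """Cross-sample recurrence of target genes and TF->target pairs.

    ``per_sample_candidates`` maps sample_id -> candidate rows. Returns
    ``{"genes": [...], "pairs": [...]}`` listing targets (and TF-target
    pairs) supported by candidates in two or more samples.
    """
    if not per_sample_candidates:
        raise ValueError("need at least one sample")
    gene_samples: dict = {}
    pair_samples: dict = {}
    for sample, rows in per_sample_candidates.items():
        for r in rows:
            gene_samples.setdefault(r["target_gene"], set()).add(sample)
            pair_samples.setdefault((r["tf"], r["target_gene"]), set()).add(sample)
    genes = [
        {"target_gene": g, "samples": sorted(s)}
        for g, s in sorted(gene_samples.items())
        if len(s) >= 2
    ]
    pairs = [
        {"tf": tf, "target_gene": g, "samples": sorted(s)}
        for (tf, g), s in sorted(pair_samples.items())
        if len(s) >= 2
    ]
    return {"genes": genes, "pairs": pairs}
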