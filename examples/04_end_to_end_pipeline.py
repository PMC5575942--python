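"""Run the whole pipeline on a synthetic dataset with one planted cis-GoF event.

The generator fabricates a genome, variants (one engineered motif-gain
insertion 7.5 kb upstream of an over-expressed target gene, plus 67 inert
background mutations and 8 dbSNP-annotated SNPs), expression, motifs,
rankings, TADs, H3K27ac peaks, and allele counts. The pipeline should report
exactly the planted variant as a candidate.
"""

import tempfile
from pathlib import Path

from mucistarget.pipeline import RunConfig, run_sample
from mucistarget.synthetic import FixtureSpec, generate_fixture

with tempfile.TemporaryDirectory() as tmp:
    fixture_dir = Path(tmp) / "fixture"
    truth = generate_fixture(FixtureSpec(seed=42), fixture_dir)
    planted = truth["planted"][0]
    print(f"planted: {planted['variant_class']} {planted['chrom']}:{planted['pos']} "
          f"{planted['ref']}>{planted['alt']} creating a {planted['motif_id']} site "
          f"{planted['distance_to_tss']} bp upstream of {planted['target_gene']}")

    config = RunConfig.from_yaml(fixture_dir / "config.yaml")
    result = run_sample(config, out_dir=Path(tmp) / "out")

    print("\nfilter funnel:")
    for stage, count in result.funnel:
        print(f"  {stage:<35}{count:>7}")

    print("\ncandidate cis-GoF mutations:")
    for c in result.candidates:
        print(f"  {c['variant_id']}: {c['tf']} motif {c['motif_id']} gained near "
              f"{c['target_gene']} (delta {c['delta']:.3f}, "
              f"in peak: {c['in_peak']}, target ASE: {c['is_ase']}, "
              f"TAD support: {c['tad_samples']})")
# Of the 76 variants, only the planted insertion survives every layer:
# master-regulator motif gain, over-expressed relevant target within 1 Mb,
# shared TAD, H3K27ac peak overlap, and allele-specific expression of the
# target gene.
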