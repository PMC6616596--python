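"""FST outlier scan with selection regions and annotation overlap.

Four demes diverged by drift; per-SNP FST is computed by the ANOVA
estimator, the top 1% of SNPs are flagged, ±200 kb regions are built
around them, and the regions are intersected with a toy gene BED.
"""

import numpy as np

import popscan as ps

demo = ps.DemographyConfig(
    populations=[ps.PopulationConfig("A", [100] * 131)] + [
        ps.PopulationConfig(lab, [100] * 130) for lab in ("B", "C", "D")],
    split_events=[ps.SplitEvent(130, "A", lab) for lab in ("B", "C", "D")],
    sample_sizes={lab: 30 for lab in "ABCD"},
)
panel = ps.simulate(demo, ps.GenomeConfig(
    chromosome_length_bp=40_000_000, n_snps=3000, seed=23))

res = ps.per_snp_fst(panel)
res = ps.call_outliers(res, quantile=0.99)
fst = res.table["fst"]
print(f"FST over {len(fst)} SNPs: mean={fst.mean():.3f} "
      f"range=[{fst.min():.3f}, {fst.max():.3f}]")
print(f"top-1% threshold: {res.threshold:.3f}; "
      f"{int(res.table['significant'].sum())} outlier SNPs")

regions = ps.build_regions(res, flank_bp=200_000)
print(f"{len(regions)} potential selection regions of <= 400 kb")

# toy annotation: a gene every 2 Mb
with open("toy_genes.bed", "w") as fh:
    for k, start in enumerate(range(0, 40_000_000, 2_000_000)):
        fh.write(f"1\t{start}\t{start + 50_000}\tGENE{k}\n")
ann = ps.read_annotation_bed("toy_genes.bed", kind="gene")
hits = ps.overlap_annotation(regions, ann)
print(f"{hits['name'].nunique()} genes overlap an outlier region")
# High-FST neighborhoods are candidate targets of divergent selection;
# overlap with annotation turns them into named candidate genes.
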