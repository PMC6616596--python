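"""Simulate a two-population SNP panel with a known history.

Two demes of 100 diploids split 150 generations ago; genotypes for
1,500 SNPs on a 25-Mb chromosome are written as PLINK files together
with a truth YAML recording the demography.
"""

import popscan as ps

demo = ps.DemographyConfig(
    populations=[ps.PopulationConfig("NORTH", [100] * 250),
                 ps.PopulationConfig("SOUTH", [100] * 150)],
    split_events=[ps.SplitEvent(generation=150, parent="NORTH",
                                child="SOUTH")],
    sample_sizes={"NORTH": 30, "SOUTH": 30},
)
genome = ps.GenomeConfig(chromosome_length_bp=25_000_000, n_snps=1500,
                         missing_rate=0.01, seed=42)

panel = ps.simulate(demo, genome)
ps.write_fixture(panel, "example_panel", demo, genome)

print(panel)
print(f"missing genotype fraction: {(panel.dosage == -1).mean():.3f}")
# Each sampled individual carries 0/1/2 copies of allele B per SNP; the
# truth file example_panel.truth.yaml records the generating history.
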