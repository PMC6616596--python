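"""Per-population diversity statistics on a simulated panel.

Prints one row per population: sample size, the number of SNPs at
intermediate frequency (N_SNP, MAF >= 0.2), the proportion of
segregating markers (P_N), observed and expected heterozygosity
(H_O, H_E), and rarefied allelic richness (A_R, between 1 and 2 for
biallelic SNPs).
"""

import popscan as ps

demo = ps.DemographyConfig(
    populations=[ps.PopulationConfig("LARGE", [200] * 150),
                 ps.PopulationConfig("SMALL", [25] * 100)],
    split_events=[ps.SplitEvent(100, "LARGE", "SMALL")],
    sample_sizes={"LARGE": 25, "SMALL": 25},
)
panel = ps.simulate(demo, ps.GenomeConfig(
    chromosome_length_bp=25_000_000, n_snps=2000, seed=7))

table = ps.diversity_table(panel)
print(table.round(3).to_string(index=False))
# The deme that spent 100 generations at size 25 loses heterozygosity
# and allelic richness relative to its large sister population.
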