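"""PCA of genotypes, including an admixed population.

The recipient of a recent 50/50 admixture pulse lands between its
donor and its unadmixed sister population on the first principal
component.
"""

import numpy as np

import popscan as ps

demo = ps.DemographyConfig(
    populations=[ps.PopulationConfig("DONOR", [100] * 400),
                 ps.PopulationConfig("SISTER", [100] * 300),
                 ps.PopulationConfig("ADMIXED", [100] * 300)],
    split_events=[ps.SplitEvent(300, "DONOR", "SISTER"),
                  ps.SplitEvent(300, "DONOR", "ADMIXED")],
    admixture_events=[ps.AdmixtureEvent(10, "ADMIXED", "DONOR", 0.5)],
    sample_sizes={"DONOR": 30, "SISTER": 30, "ADMIXED": 30},
)
panel = ps.simulate(demo, ps.GenomeConfig(
    chromosome_length_bp=20_000_000, n_snps=1500, seed=51))

res = ps.pca(panel, k=5)
print("variance contributions:",
      ", ".join(f"pc{i+1}={c:.1%}" for i, c in
                enumerate(res.contributions[:3])))

pops = panel.samples["population"].to_numpy()
for pop in ("DONOR", "ADMIXED", "SISTER"):
    mean_pc1 = res.coordinates[pops == pop, 0].mean()
    print(f"{pop:8s} mean pc1 = {mean_pc1:+.3f}")
# The ADMIXED mean lies strictly between DONOR and SISTER: half its
# recent ancestry comes from the donor deme.
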