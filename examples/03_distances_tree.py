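"""Genetic distances and a neighbor-joining tree of populations.

Three demes with nested split times: the more recently separated pair
should show the smallest Nei distance and pair together in the tree.
"""

import popscan as ps

demo = ps.DemographyConfig(
    populations=[ps.PopulationConfig("A", [100] * 300),
                 ps.PopulationConfig("B", [100] * 200),
                 ps.PopulationConfig("C", [100] * 50)],
    split_events=[ps.SplitEvent(200, "A", "B"),
                  ps.SplitEvent(50, "B", "C")],
    sample_sizes={"A": 20, "B": 20, "C": 20},
)
panel = ps.simulate(demo, ps.GenomeConfig(
    chromosome_length_bp=25_000_000, n_snps=2000, seed=11))

dm = ps.nei_distance(panel)
print("Nei standardized distances:")
print(dm.to_frame().round(4))

tree = ps.neighbor_joining(dm)
print("\nneighbor-joining tree:", tree.to_newick())

ind = ps.ibs_distance(panel)
print(f"\nmean allele-sharing distance between individuals: "
      f"{ind.values[ind.values > 0].mean():.3f}")
# B and C split only 50 generations ago, so Dxy(B,C) is the smallest
# entry and (B,C) form a cherry in the newick string.
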