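"""LD decay and LD-based historical effective population size.

Simulates a constant population of Ne = 100, bins genotype r² by
physical distance, fits the 4-parameter decay curve, and inverts
Sved's relation to a trajectory of historical Ne — which should hover
near the true value of 100.
"""

import numpy as np

import popscan as ps

panel = ps.simulate(
    ps.constant_demography("P", size=100, n_generations=250, n_sampled=50),
    ps.GenomeConfig(chromosome_length_bp=50_000_000, n_snps=5000,
                    recombination_rate=1e-8, seed=1))

keep = np.flatnonzero(ps.mafs(panel) >= 0.05)
pairs = ps.pairwise_r2(panel.subset(marker_idx=keep))
print(f"{len(pairs):,} SNP pairs within 20 Mb")

bins = ps.bin_ld(pairs)
fit = ps.fit_ld_decay(bins)
print(f"decay fit: a={fit.a:.3f} b={fit.b:.3f} c={fit.c / 1e6:.2f}Mb "
      f"d={fit.d:.3f}  R^2={fit.r_squared_of_fit:.3f}")

traj = ps.ne_trajectory(fit, t_min=3, t_max=100)
sel = traj[(traj["t"] >= 10) & (traj["t"] <= 50)]
print(f"median Ne over generations 10-50: {sel['ne'].median():.1f} "
      f"(truth: 100)")
for t in (5, 10, 25, 50, 100):
    row = traj[traj["t"] == t].iloc[0]
    print(f"  t={t:3d}  E[r2]={row['predicted_r2']:.4f}  "
          f"Ne={row['ne']:.1f}")
# Short-range LD informs the distant past, long-range LD the recent
# past; under a constant-size history all generations give ~100.
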