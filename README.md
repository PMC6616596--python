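# popscan

Population-genetics analysis of SNP-chip genotype panels, built for
conservation-genetics studies of livestock breeds (the motivating case is
indigenous pig populations genotyped on 60–80K SNP arrays, compared with
commercial and wild populations). It is a library first — every stage is a
plain Python function over a `GenotypePanel` — with a thin `popscan` CLI and
an end-to-end pipeline runner on top.

## What it computes

* **Panel handling** — PLINK text (`ped`/`map`) and binary (`bed`/`bim`/`fam`)
  reading and writing, multi-chip marker intersection with allele
  harmonization, and stepwise QC (SNP call rate → MAF → sample call rate).
* **Diversity** — per population: N_SNP (markers with MAF ≥ 0.2), P_N
  (proportion polymorphic), observed and expected heterozygosity
  (H_O, and H_E = 2p(1−p)), and allelic richness A_R by hypergeometric
  rarefaction to g gene copies:
  A_R = Σ_i [1 − C(N−N_i, g)/C(N, g)].
* **Distances and trees** — individual allele-sharing distance
  D = 1 − (IBS2 + 0.5·IBS1)/N; Nei's standardized distance
  D_xy = −ln[ Σ x_ij y_ij / √(Σ x_ij² · Σ y_ij²) ]; Saitou–Nei
  neighbor joining with newick output.
* **PCA** — eigendecomposition of the standardized genomic relationship
  matrix G_jk = (1/M) Σ_m (x_jm − 2p_m)(x_km − 2p_m) / (2p_m(1−p_m)),
  with per-component variance contributions.
* **LD decay and historical Ne** — genotype r² (squared Pearson correlation
  of dosages) for all intra-chromosomal pairs within 20 Mb, averaged in
  0.2-Mb bins; a 4-parameter decay fit
  r²(dist) = (a−d)/(1+(dist/c)^b) + d; and historical effective size by
  Sved's relation Ne(t) = (1/(k·m))·(1/E[r²] − α) with m = 1/(2t) and
  m = dist·(1 − dist/2) linking recombination frequency to map distance.
* **FST outlier scan** — per-SNP ANOVA estimator
  F_ST = (MSP − MSG)/(MSP + (n_C − 1)·MSG), empirical top-1% outliers,
  ±200 kb selection regions, and overlap with gene/QTL BED annotation.
* **Wright–Fisher simulator** — forward-in-time diploid simulation with
  recombination, arbitrary size trajectories, splits, admixture pulses and
  missingness, so every stage can be validated against a known truth.

## Worked example

`examples/05_ld_ne.py` simulates a constant population of Ne = 100
(50 Mb chromosome, 5,000 SNPs, r = 10⁻⁸/bp, 50 individuals sampled), fits
the LD decay curve and inverts it to a trajectory of historical Ne:

```
1,058,830 SNP pairs within 20 Mb
decay fit: a=0.674 b=1.402 c=0.51Mb d=0.033  R^2=0.995
median Ne over generations 10-50: 94.9 (truth: 100)
  t=  5  E[r2]=0.0421  Ne=56.9
  t= 10  E[r2]=0.0573  Ne=82.2
  t= 25  E[r2]=0.1145  Ne=96.7
  t= 50  E[r2]=0.2120  Ne=92.9
  t=100  E[r2]=0.3579  Ne=89.7
```

`a` and `d` are the short- and long-range r² asymptotes, `c` the half-decay
distance and `b` the decay shape; the fit explains 99.5% of the variance in
the binned means. Long-distance LD reflects recent generations and
short-distance LD the distant past, so a constant-size history yields a
flat trajectory near the truth — here the median over generations 10–50 is
94.9 against a true value of 100. The other scripts in `examples/` walk
through simulation, diversity tables, distance trees, PCA of admixed
populations, the FST scan, and the one-call pipeline.

Command-line equivalents:

```bash
popscan simulate --config demo.yaml --out fixtures/run1
popscan qc --in fixtures/run1 --format bed --out fixtures/clean
popscan ldne --in fixtures/clean --group P --out results/p
popscan fst --in fixtures/clean --top 0.01 --out results/scan
popscan run --config run.yaml          # full pipeline with manifest caching
```

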