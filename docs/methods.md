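# Methods

This note documents the statistical models, the conventions chosen where
several were defensible, the synthetic-data generator and what its tests
do and do not demonstrate, and the numerical details that affect results.

## Genotype panels and quality control

A panel is an individuals × markers matrix of allele-B dosages (0/1/2,
−1 missing) with marker metadata (id, chromosome label, 1-based bp
position, allele pair) and sample metadata (id, population, sex). Markers
are kept sorted by (chromosome, position); all physical distances
downstream are plain position differences in bp. Only markers whose
chromosome label parses as an autosome (1–18 by default, the pig
karyotype) enter PCA, LD and FST stages.

QC applies three filters in a fixed, reported order: (1) drop SNPs with
call rate below threshold (default 0.90), (2) drop SNPs with MAF below
threshold (default 0.05) computed over all samples, (3) drop samples with
call rate below threshold (default 0.90) over the retained SNPs. The
order matters when missingness is concentrated; it is fixed so runs are
comparable, and the report lists counts removed at each step. One pass is
not mathematically idempotent (removing a sample can nudge a SNP's call
rate), but is in practice on well-behaved panels; the pipeline runs a
single pass, as the cited thresholds imply.

Merging chips intersects marker ids and harmonizes allele order against
the first panel (dosage flip d → 2−d when the pair is swapped). Strand
ambiguity is not resolved: a marker whose allele pairs differ by more
than a swap is dropped with a warning, because A/T and C/G pairs cannot
be disambiguated without frequency heuristics we prefer not to hide.

PLINK I/O is implemented directly (text ped/map and the v1.00 SNP-major
bed layout). The ped format carries no allele ordering, so the reader
adopts a deterministic convention — alleles sorted lexically — and a
marker fixed for its B allele round-trips through ped with its
orientation flipped (bed round-trips exactly).

## Diversity statistics

Per population, on a designated marker subset (typically the markers at
MAF ≥ 0.2 in two reference groups, to blunt chip ascertainment):

* H_O: fraction of heterozygous calls, averaged over markers.
* H_E: 2p(1−p) from the within-population frequency, averaged over
  markers. The plain estimator is the default; the unbiased
  2p(1−p)·2n/(2n−1) variant is available behind a flag.
* P_N: fraction of markers with 0 < p < 1 within the population. The
  threshold is exactly zero (any segregation counts), which is the only
  reading consistent with P_N = 1 coexisting with N_SNP well below the
  marker count.
* N_SNP: count of markers with within-population MAF ≥ 0.2.
* A_R: hypergeometric rarefaction. For a marker with N non-missing gene
  copies, N_i of allele i, the expected allele count in g sampled copies
  is Σ_i [1 − C(N−N_i, g)/C(N, g)], computed via log-gamma for
  stability. g defaults to twice the smallest per-population sample size
  when a whole table is produced (so rows are comparable), clamped per
  population to the copies actually available at its worst marker.
  Rarefaction depends on N as well as the frequencies, so A_R is not
  exactly invariant under duplicating every individual — the
  frequency-based statistics are.

## Distances and trees

The individual distance is allele-sharing: over loci called in both
individuals, D = 1 − (IBS2 + 0.5·IBS1)/N, which reduces to
mean(|d_i − d_j|)/2 on dosages. Pairs with zero jointly called loci are
an error, not a silent NaN.

Nei's standardized distance between populations x and y sums over loci
and both alleles: D_xy = −ln[J_xy / √(J_x·J_y)] with J_xy = Σ x_ij y_ij
etc. Loci untyped in either population are excluded pairwise. Disjoint
fixation makes the identity coefficient 0; the distance is reported as
+inf with a warning rather than raising, since downstream consumers may
still use the finite entries.

Neighbor joining is the classic Saitou–Nei agglomeration on the
Q-criterion. Ties in the Q minimum are broken by the lowest (row,
column) pair, making output deterministic. Estimated negative branch
lengths are clamped to zero. The final three nodes get closed-form
lengths and form the root trifurcation of the (unrooted) tree. On
additive matrices the generating topology and lengths are recovered
exactly; this is tested against dendropy-generated trees and cross-checked
against scikit-bio's implementation on non-additive noise.

## PCA

The relationship matrix uses GCTA-style standardization
(x − 2p)/√(2p(1−p)) with pooled frequencies, mean imputation of missing
dosages, and monomorphic markers skipped; a plain covariance variant is
available. Components come from `eigh`; coordinates are eigenvectors
scaled by √λ and contributions are eigenvalue shares of the positive
spectrum. Eigenvector sign is arbitrary, so tests assert separation and
betweenness, never signs.

## LD decay and historical Ne

Genotype r² is the squared Pearson correlation of dosage vectors —
appropriate when phase is unknown, as for SNP-chip data — over jointly
non-missing samples, for intra-chromosomal pairs within 20 Mb. Pairs with
a monomorphic member or fewer than 3 joint samples are skipped and
counted. The computation is blocked matrix algebra (mask-aware when
missingness is present), so million-pair panels take seconds. No
sample-size correction is applied to r² by default (an r² − 1/(2n)
adjustment exists behind a flag).

Pairs are averaged in 100 half-open bins (lower, upper] of 0.2 Mb up to
20 Mb; a pair at exactly 200,000 bp belongs to bin 1. Empty bins carry
pair_count 0 and are excluded from fitting. The decay model

    r²(dist) = (a − d)/(1 + (dist/c)^b) + d

is fitted to the binned means (unweighted by default; √pair-count
weighting optional) by bounded least squares (a, d ∈ [0,1], b ∈
(10⁻³, 20], c > 1) from a deterministic 3×3 multi-start grid: b ∈
{0.5, 1, 2} crossed with log-spaced c spanning the observed distances;
lowest residual wins, earlier starts win ties. A constant table
degenerates to a = d = mean r² with fit R² = 0 by convention. Fit R² is
1 − SSres/SStot over non-empty bins.

The Ne trajectory evaluates, for each generation t in 3..100:
m = 1/(2t); map distance by inverting Sved's m = dist·(1 − dist/2)
(dist = 1 − √(1−2m), the root in [0,1]); bp distance at 1 cM/Mb
(morgans_per_bp = 10⁻⁸, configurable); E[r²] from the fitted curve (not
raw bins — a raw-bin mode exists for diagnostics); and

    Ne(t) = 1/(k·m) · (1/E[r²] − α).

Defaults k = 4 (Sved's E[r²] = 1/(1 + 4Nc)) and α = 1 (no-mutation
adjustment; α = 2 gives the mutation-adjusted variant). Rows where
E[r²] ≤ 0 or 1/E[r²] ≤ α are flagged invalid and kept, never silently
dropped. Fitting pools pairs genome-wide rather than per chromosome.

## FST scan

Per SNP, a one-way ANOVA on gene copies (each allele copy an observation
scored 0/1): with group copy counts N_g, frequencies p_g, r groups,
N = Σ N_g,

    MSP = Σ N_g (p_g − p̄)² / (r − 1)
    MSG = Σ N_g p_g (1 − p_g) / (N − r)
    n_C = (N − Σ N_g²/N) / (r − 1)
    F_ST = (MSP − MSG) / (MSP + (n_C − 1)·MSG)

Negative estimates are reported as computed — only the upper tail drives
outlier calling. Groups with no data at a SNP are excluded for that SNP;
SNPs observed in fewer than two groups get NaN. A zero denominator
yields 0. Per-SNP ratios carry a small Jensen bias relative to drift
theory; the multilocus ratio-of-sums combination is used when comparing
to theoretical expectations in tests.

Outliers are the top floor((1−q)·M) SNPs by FST (default q = 0.99) among
the M finite values, ties at the cut broken by (chromosome, position);
the threshold reported is the smallest flagged value. Each outlier SNP
defines one ±200 kb region (never merged, clipped at position 1).
Annotation BED files are 0-based half-open on disk and converted to the
internal 1-based inclusive convention at the boundary; overlap means
sharing at least one bp.

## Wright–Fisher simulator

Forward-in-time, discrete generations, diploid. Each offspring draws two
parents uniformly with replacement; each gamete recombines by a Poisson
crossover process at a constant per-bp rate (default 10⁻⁸, i.e. 1 cM/Mb).
Founders are at linkage equilibrium with frequencies uniform on
[0.05, 0.95], mimicking common-variant array ascertainment. No mutation
occurs during the simulated epoch. Splits copy a parent deme's gene pool
at a stated generation before sampling; an admixture event redirects a
fraction of one generation's parent draws to a donor deme. Missingness
is i.i.d. Output is fully deterministic given the seed (single
`numpy.random.Generator` stream, fixed iteration order).

Forward simulation was chosen over a coalescent because arbitrary size
trajectories and admixture timing are then exact by construction. The
default test genome is one 50-Mb chromosome with 5,000 SNPs — large
enough for 20-Mb LD binning, small enough for minutes-scale suites.

What the generator emulates: drift at known Ne per generation,
recombination-structured LD, divergence under splits, admixture pulses,
array-like common-variant spectra, missingness. What it does not:
mutation, selection, non-uniform recombination maps, overlapping
generations, and real chip ascertainment quirks beyond the founder
spectrum. Passing recovery tests therefore demonstrates the estimators'
correctness under the model's own assumptions, not robustness to
everything real data can do.

## Calibration of the recovery checks

Study conditions for the end-to-end Ne recovery: constant-size runs use
250 generations of burn-in (enough for LD at c ≥ 0.01 to approach
equilibrium at N = 100); the bottleneck scenario holds N = 500 for 130
generations then N = 50 for the final 20. With 5,000 SNPs on 50 Mb and
50 sampled diploids, the median estimated Ne over generations 10–50 sits
within ±40% of the truth per seed (tolerance set by pilot runs — LD-based
Ne is noisy at this panel size), and bottleneck runs show recent Ne below
ancient Ne. Drift calibration uses 20 independent chromosomes to
decorrelate loci (a single non-recombining chromosome is one gene tree,
whose shared randomness dominates the variance of any per-locus average)
and averages over seeds; increment-variance and heterozygosity-decay
ratios match 1 within 10%.

## Pipeline

`run_pipeline` executes QC → diversity → distances/trees → PCA → LD/Ne →
FST from one validated config. Each stage records a sha256 key of the
input files, parameters and package version in `manifest.json`; a rerun
with matching key and intact outputs skips the stage. Failures halt with
the stage name, preserving completed outputs.

## Known limitations

* No VCF input, imputation, phasing or liftover; no haplotype-based LD
  (D′) or selection statistics (iHS, XP-EHH); no model-based ancestry
  clustering; no gene-set enrichment.
* The exact n_C convention differs across published FST software; the
  gene-copy ANOVA here matches the printed mean-square combination but
  third-decimal differences from other tools are possible.
* Ped round-trips are exact only up to allele orientation for markers
  fixed in the written panel (format limitation).
* Nei distances of +inf (disjoint fixation) prevent tree building for
  the affected label sets.
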