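"""Per-population diversity statistics on a SNP panel.

Five standard parameters are computed per population on a designated
marker subset: the proportion of polymorphic markers (P_N), the number
of SNPs with MAF at or above a threshold (N_SNP), observed and expected
heterozygosity (H_O, H_E), and rarefied allelic richness (A_R).

To compare chip-ascertained groups fairly, analyses are usually run on
the common subset of SNPs that are at intermediate frequency in both a
"reference" group and the group of interest (see
:func:`common_high_maf_subset`); A_R uses hypergeometric rarefaction to
a common number of sampled gene copies so that populations of different
sizes are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import MISSING, GenotypePanel, PanelError

logger = logging.getLogger(__name__)


@dataclass
class DiversityReport:
    population_label: str
    n_samples: int
    n_snp_maf_ge_threshold: int
    proportion_polymorphic: float
    observed_heterozygosity: float
    expected_heterozygosity: float
    allelic_richness: float
    maf_threshold_used: float
    rarefaction_size_used: int

    def to_row(self) -> dict:
        return {
            "population": self.population_label,
            "n": self.n_samples,
            "N_SNP": self.n_snp_maf_ge_threshold,
            "P_N": self.proportion_polymorphic,
            "H_O": self.observed_heterozygosity,
            "H_E": self.expected_heterozygosity,
            "A_R": self.allelic_richness,
            "maf_threshold": self.maf_threshold_used,
            "rarefaction_g": self.rarefaction_size_used,
        }


def _subset_dosage(panel: GenotypePanel, samples, markers) -> np.ndarray:
    d = panel.dosage
    if samples is not None:
        d = d[np.asarray(samples), :]
    if markers is not None:
        d = d[:, np.asarray(markers)]
    return d


def common_high_maf_subset(panel: GenotypePanel,
                           group_a: Sequence[int],
                           group_b: Sequence[int],
                           threshold: float = 0.200) -> np.ndarray:
    """Markers with MAF >= threshold within *both* sample groups.

    Returns marker column indices (into ``panel.markers``). Emits a
    warning and returns an empty array when no marker qualifies.
    """
    group_a, group_b = np.asarray(group_a), np.asarray(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise PanelError("common_high_maf_subset: empty group")
    pa = panel.allele_b_frequencies(sample_idx=group_a)
    pb = panel.allele_b_frequencies(sample_idx=group_b)
    maf_a = np.minimum(pa, 1 - pa)
    maf_b = np.minimum(pb, 1 - pb)
    with np.errstate(invalid="ignore"):
        keep = (maf_a >= threshold) & (maf_b >= threshold)
    keep &= ~np.isnan(maf_a) & ~np.isnan(maf_b)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        logger.warning("common_high_maf_subset: no marker passes MAF >= %s "
                       "in both groups", threshold)
    return idx


def heterozygosities(panel: GenotypePanel,
                     samples: Sequence[int] | None = None,
                     markers: Sequence[int] | None = None,
                     unbiased: bool = False) -> tuple[float, float]:
    """Mean observed and expected heterozygosity over a marker subset.

    Per marker, H_O is the fraction of non-missing genotypes that are
    heterozygous and H_E = 2p(1-p) with p the within-subset allele-b
    frequency; both are averaged across markers. With ``unbiased=True``
    H_E carries the small-sample factor 2n/(2n-1).
    """
    d = _subset_dosage(panel, samples, markers)
    if d.shape[1] == 0:
        raise PanelError("heterozygosities: empty marker subset")
    obs = d != MISSING
    n = obs.sum(axis=0)
    if (n == 0).any():
        raise PanelError("heterozygosities: marker with all genotypes missing")
    ho = (d == 1).sum(axis=0) / n
    p = np.where(obs, d, 0).sum(axis=0) / (2.0 * n)
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        he = he * (2.0 * n) / (2.0 * n - 1.0)
    return float(ho.mean()), float(he.mean())


def proportion_polymorphic(panel: GenotypePanel,
                           samples: Sequence[int] | None = None,
                           markers: Sequence[int] | None = None) -> float:
    """Fraction of markers segregating (MAF > 0) within the subset."""
    d = _subset_dosage(panel, samples, markers)
    if d.shape[1] == 0:
        raise PanelError("proportion_polymorphic: empty marker subset")
    obs = d != MISSING
    n = obs.sum(axis=0)
    tot = np.where(obs, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, tot / (2.0 * n), np.nan)
    poly = (p > 0) & (p < 1)
    return float(poly.sum() / d.shape[1])


def allelic_richness(panel: GenotypePanel,
                     samples: Sequence[int] | None = None,
                     markers: Sequence[int] | None = None,
                     rarefaction_size: int | None = None) -> float:
    """Mean rarefied allele count per marker (hypergeometric rarefaction).

    For a marker with N non-missing gene copies of which N_i carry
    allele i, the expected number of distinct alleles in a random draw
    of g copies is sum_i [1 - C(N - N_i, g) / C(N, g)], with C(x, g) = 0
    for x < g. The value lies in [1, 2] for biallelic markers and is
    averaged over the marker subset.

    ``rarefaction_size`` (g) defaults to the smallest number of
    non-missing gene copies over the subset's markers, the largest g
    valid at every marker.
    """
    d = _subset_dosage(panel, samples, markers)
    if d.shape[1] == 0:
        raise PanelError("allelic_richness: empty marker subset")
    obs = d != MISSING
    n_copies = 2 * obs.sum(axis=0)          # N per marker
    if (n_copies == 0).any():
        raise PanelError("allelic_richness: marker with all genotypes missing")
    nb = np.where(obs, d, 0).sum(axis=0)     # copies of allele_b
    na = n_copies - nb
    if rarefaction_size is None:
        rarefaction_size = int(n_copies.min())
    g = int(rarefaction_size)
    if g < 1:
        raise PanelError("allelic_richness: rarefaction size must be >= 1")
    if g > n_copies.min():
        raise PanelError(
            f"allelic_richness: g={g} exceeds the smallest marker's "
            f"{n_copies.min()} non-missing gene copies")

    def log_comb(x: np.ndarray, k: int) -> np.ndarray:
        # log C(x, k); -inf where x < k
        x = np.asarray(x, dtype=float)
        with np.errstate(invalid="ignore"):
            out = gammaln(x + 1) - gammaln(x - k + 1) - gammaln(k + 1)
        return np.where(x >= k, out, -np.inf)

    log_cn = log_comb(n_copies, g)
    per_allele = []
    for counts in (na, nb):
        ratio = np.exp(log_comb(n_copies - counts, g) - log_cn)
        per_allele.append(1.0 - ratio)
    richness = per_allele[0] + per_allele[1]
    return float(richness.mean())


def diversity_report(panel: GenotypePanel,
                     population_label: str,
                     markers: Sequence[int] | None = None,
                     maf_threshold: float = 0.200,
                     rarefaction_size: int | None = None,
                     unbiased_he: bool = False) -> DiversityReport:
    """Assemble the five diversity parameters for one population."""
    samples = panel.samples_of(population_label)
    if samples.size < 2:
        raise PanelError(
            f"population {population_label!r} has {samples.size} samples; "
            "need >= 2")
    if markers is None:
        markers = np.arange(panel.n_markers)
    markers = np.asarray(markers)

    p = panel.allele_b_frequencies(sample_idx=samples, marker_idx=markers)
    m = np.minimum(p, 1 - p)
    with np.errstate(invalid="ignore"):
        n_snp = int(np.nansum(m >= maf_threshold))

    ho, he = heterozygosities(panel, samples, markers, unbiased=unbiased_he)
    pn = proportion_polymorphic(panel, samples, markers)

    d = _subset_dosage(panel, samples, markers)
    n_copies_min = int(2 * (d != MISSING).sum(axis=0).min())
    g = rarefaction_size if rarefaction_size is not None else n_copies_min
    if g > n_copies_min:
        # a requested common g can exceed what missing data leave at the
        # worst marker of this population; rarefy to what is available
        logger.info("diversity_report(%s): clamping rarefaction g from %d "
                    "to %d copies", population_label, g, n_copies_min)
        g = n_copies_min
    ar = allelic_richness(panel, samples, markers, rarefaction_size=g)

    return DiversityReport(
        population_label=population_label,
        n_samples=int(samples.size),
        n_snp_maf_ge_threshold=n_snp,
        proportion_polymorphic=pn,
        observed_heterozygosity=ho,
        expected_heterozygosity=he,
        allelic_richness=ar,
        maf_threshold_used=maf_threshold,
        rarefaction_size_used=int(g),
    )


def diversity_table(panel: GenotypePanel,
                    markers: Sequence[int] | None = None,
                    maf_threshold: float = 0.200,
                    rarefaction_size: int | None = None) -> pd.DataFrame:
    """One diversity row per population label present in the panel.

    When ``rarefaction_size`` is None a single common g — twice the
    smallest per-population sample size — is used for every population
    so the A_R column is comparable across rows.
    """
    pops = panel.samples["population"].unique().tolist()
    if rarefaction_size is None:
        smallest = min(panel.samples_of(p).size for p in pops)
        rarefaction_size = 2 * smallest
    rows = [
        diversity_report(panel, pop, markers, maf_threshold,
                         rarefaction_size=rarefaction_size).to_row()
        for pop in pops
    ]
    return pd.DataFrame(rows)
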