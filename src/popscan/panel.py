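"""Core genotype-panel container and quality control.

A :class:`GenotypePanel` holds diploid biallelic genotypes as an
``individuals x markers`` dosage matrix counting copies of ``allele_b``
(0, 1, 2, or -1 for missing), together with marker and sample metadata.
It is the substrate for every downstream analysis stage (diversity,
distances, PCA, LD/Ne, FST).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: columns of the marker metadata table
MARKER_COLUMNS = ["id", "chromosome", "position", "allele_a", "allele_b"]
#: columns of the sample metadata table
SAMPLE_COLUMNS = ["individual_id", "population", "sex"]

SEX_CODES = {"male", "female", "unknown"}


class PanelError(ValueError):
    """Raised for invalid panel construction or panel operations."""


def _chromosome_sort_key(labels: pd.Series) -> pd.Series:
    """Numeric chromosome labels sort numerically, others lexically after."""
    numeric = pd.to_numeric(labels, errors="coerce")
    is_num = numeric.notna()
    # non-numeric labels (X, MT, ...) go after autosomes, alphabetically
    return pd.Series(
        [(0, float(n), "") if ok else (1, 0.0, str(l))
         for l, n, ok in zip(labels, numeric, is_num)],
        index=labels.index,
    )


@dataclass
class QCConfig:
    """Thresholds for panel quality control.

    Defaults follow common SNP-chip practice: markers must be called in
    90% of individuals and have minor allele frequency >= 5%; individuals
    must be genotyped at 90% of retained markers.
    """

    min_snp_call_rate: float = 0.900
    min_maf: float = 0.050
    min_sample_call_rate: float = 0.900

    def __post_init__(self) -> None:
        for name in ("min_snp_call_rate", "min_maf", "min_sample_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    """Counts of markers/samples dropped at each QC step."""

    n_markers_in: int
    n_samples_in: int
    n_snp_dropped_call_rate: int
    n_snp_dropped_maf: int
    n_samples_dropped_call_rate: int
    n_markers_out: int
    n_samples_out: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [
                    "input",
                    "snp_call_rate",
                    "snp_maf",
                    "sample_call_rate",
                    "output",
                ],
                "markers": [
                    self.n_markers_in,
                    -self.n_snp_dropped_call_rate,
                    -self.n_snp_dropped_maf,
                    0,
                    self.n_markers_out,
                ],
                "samples": [
                    self.n_samples_in,
                    0,
                    0,
                    -self.n_samples_dropped_call_rate,
                    self.n_samples_out,
                ],
            }
        )


@dataclass
class MergeReport:
    """Bookkeeping from :func:`intersect_panels`."""

    n_markers_common: int
    n_markers_flipped: int
    n_markers_dropped_irreconcilable: int
    dropped_ids: list[str] = field(default_factory=list)


class GenotypePanel:
    """Diploid biallelic SNP genotypes for a set of individuals.

    Parameters
    ----------
    markers
        DataFrame with columns ``id, chromosome, position, allele_a,
        allele_b``. Positions are 1-based bp as in PLINK map/bim files.
    samples
        DataFrame with columns ``individual_id, population, sex``.
    dosage
        ``(n_samples, n_markers)`` integer matrix counting copies of
        ``allele_b`` per genotype; ``-1`` encodes a missing call.

    Markers are sorted by (chromosome, position) at construction, so all
    downstream physical distances are simple position differences.
    """

    def __init__(self, markers: pd.DataFrame, samples: pd.DataFrame,
                 dosage: np.ndarray):
        markers = markers.reset_index(drop=True).copy()
        samples = samples.reset_index(drop=True).copy()
        dosage = np.asarray(dosage)

        missing_cols = set(MARKER_COLUMNS) - set(markers.columns)
        if missing_cols:
            raise PanelError(f"marker table missing columns {missing_cols}")
        missing_cols = set(SAMPLE_COLUMNS) - set(samples.columns)
        if missing_cols:
            raise PanelError(f"sample table missing columns {missing_cols}")

        if dosage.shape != (len(samples), len(markers)):
            raise PanelError(
                f"dosage shape {dosage.shape} != "
                f"({len(samples)}, {len(markers)})"
            )
        dosage = dosage.astype(np.int8, copy=False)
        bad = ~np.isin(dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise PanelError(
                f"{bad.sum()} dosage entries outside {{-1,0,1,2}}"
            )
        if markers["id"].duplicated().any():
            dups = markers.loc[markers["id"].duplicated(), "id"].tolist()[:5]
            raise PanelError(f"duplicate marker ids: {dups} ...")
        if samples["individual_id"].duplicated().any():
            raise PanelError("duplicate individual ids")
        if (markers["position"] < 1).any():
            raise PanelError("marker positions must be >= 1")
        if (markers["chromosome"].astype(str).str.len() == 0).any():
            raise PanelError("empty chromosome label")
        bad_sex = ~samples["sex"].isin(SEX_CODES)
        if bad_sex.any():
            raise PanelError(
                f"invalid sex codes: {samples.loc[bad_sex, 'sex'].unique()}"
            )

        markers["position"] = markers["position"].astype(np.int64)
        markers["chromosome"] = markers["chromosome"].astype(str)

        order = markers.assign(_k=_chromosome_sort_key(markers["chromosome"]))
        order = order.sort_values(["_k", "position"], kind="stable").index
        self.markers = markers.loc[order].reset_index(drop=True)
        self.samples = samples
        self.dosage = np.ascontiguousarray(
            dosage[:, np.asarray(order, dtype=np.intp)])

    # -- basics --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def __repr__(self) -> str:
        return (f"GenotypePanel({self.n_samples} samples x "
                f"{self.n_markers} markers)")

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.markers.equals(other.markers)
            and self.samples.equals(other.samples)
            and np.array_equal(self.dosage, other.dosage)
        )

    def subset(self, sample_idx: Sequence[int] | None = None,
               marker_idx: Sequence[int] | None = None) -> "GenotypePanel":
        """Return a new panel restricted to the given index arrays."""
        s = np.arange(self.n_samples) if sample_idx is None else \
            np.asarray(sample_idx, dtype=np.intp)
        m = np.arange(self.n_markers) if marker_idx is None else \
            np.asarray(marker_idx, dtype=np.intp)
        return GenotypePanel(
            self.markers.iloc[m],
            self.samples.iloc[s],
            self.dosage[np.ix_(s, m)],
        )

    def samples_of(self, population: str) -> np.ndarray:
        """Row indices of all individuals with the given population label."""
        return np.flatnonzero(self.samples["population"].to_numpy() == population)

    def autosome_markers(self, n_autosomes: int = 18) -> np.ndarray:
        """Column indices of markers on autosomes ``1..n_autosomes``.

        Chromosome labels that do not parse as an integer in that range
        (X, Y, MT, unplaced scaffolds) are excluded. The default of 18
        matches the pig karyotype.
        """
        num = pd.to_numeric(self.markers["chromosome"], errors="coerce")
        keep = num.notna() & (num >= 1) & (num <= n_autosomes)
        return np.flatnonzero(keep.to_numpy())

    # -- allele frequencies --------------------------------------------

    def allele_b_frequencies(self, sample_idx: Sequence[int] | None = None,
                             marker_idx: Sequence[int] | None = None
                             ) -> np.ndarray:
        """Per-marker frequency of allele_b over non-missing genotypes.

        Markers with no non-missing genotype in the subset yield NaN.
        """
        d = self.dosage
        if sample_idx is not None:
            d = d[np.asarray(sample_idx), :]
        if marker_idx is not None:
            d = d[:, np.asarray(marker_idx)]
        obs = d != MISSING
        n = obs.sum(axis=0)
        tot = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def call_rates(self, axis: str = "marker") -> np.ndarray:
        """Fraction of non-missing genotypes per marker or per sample."""
        obs = self.dosage != MISSING
        if axis == "marker":
            return obs.mean(axis=0)
        if axis == "sample":
            return obs.mean(axis=1)
        raise ValueError("axis must be 'marker' or 'sample'")


def maf(panel: GenotypePanel, marker_index: int,
        sample_idx: Sequence[int] | None = None) -> float:
    """Minor allele frequency min(p, 1-p) at one marker.

    Raises :class:`PanelError` if every genotype at the marker is missing.
    """
    p = panel.allele_b_frequencies(sample_idx=sample_idx,
                                   marker_idx=[marker_index])[0]
    if np.isnan(p):
        raise PanelError(f"marker {marker_index}: all genotypes missing")
    return float(min(p, 1.0 - p))


def mafs(panel: GenotypePanel,
         sample_idx: Sequence[int] | None = None) -> np.ndarray:
    """Vector of minor allele frequencies for all markers (NaN if unobserved)."""
    p = panel.allele_b_frequencies(sample_idx=sample_idx)
    return np.minimum(p, 1.0 - p)


def apply_qc(panel: GenotypePanel,
             config: QCConfig | None = None) -> tuple[GenotypePanel, QCReport]:
    """Quality-filter a panel, in a fixed, documented order.

    1. drop markers with call rate below ``min_snp_call_rate``;
    2. drop markers with MAF (over all samples) below ``min_maf``;
    3. drop samples with call rate over the retained markers below
       ``min_sample_call_rate``.

    Returns the filtered panel and a stepwise :class:`QCReport`.
    Raises :class:`PanelError` if nothing survives.
    """
    config = config or QCConfig()
    if panel.n_markers == 0 or panel.n_samples == 0:
        raise PanelError("apply_qc: empty panel")

    obs = panel.dosage != MISSING
    snp_cr = obs.mean(axis=0)
    keep1 = snp_cr >= config.min_snp_call_rate
    n_drop_cr = int((~keep1).sum())

    m = mafs(panel)
    keep2 = keep1 & ~np.isnan(m) & (m >= config.min_maf)
    n_drop_maf = int(keep1.sum() - keep2.sum())

    marker_idx = np.flatnonzero(keep2)
    if marker_idx.size == 0:
        raise PanelError("QC removed everything (no markers left)")

    sample_cr = obs[:, marker_idx].mean(axis=1)
    keep_s = sample_cr >= config.min_sample_call_rate
    n_drop_s = int((~keep_s).sum())
    sample_idx = np.flatnonzero(keep_s)
    if sample_idx.size == 0:
        raise PanelError("QC removed everything (no samples left)")

    out = panel.subset(sample_idx, marker_idx)
    report = QCReport(
        n_markers_in=panel.n_markers,
        n_samples_in=panel.n_samples,
        n_snp_dropped_call_rate=n_drop_cr,
        n_snp_dropped_maf=n_drop_maf,
        n_samples_dropped_call_rate=n_drop_s,
        n_markers_out=out.n_markers,
        n_samples_out=out.n_samples,
    )
    return out, report


def intersect_panels(panels: Iterable[GenotypePanel],
                     return_report: bool = False):
    """Merge panels on the markers common to all of them.

    The marker set of the result is the intersection of marker ids; the
    sample set is the concatenation of all input samples. Allele
    orientation is harmonized against the first panel: a marker typed as
    (A,G) in one panel and (G,A) in another has its dosages flipped
    (d -> 2-d). Markers whose allele pairs cannot be reconciled by a swap
    are dropped with a warning and counted in the :class:`MergeReport`.
    """
    panels = list(panels)
    if len(panels) < 2:
        raise PanelError("intersect_panels needs at least 2 panels")

    common = set(panels[0].markers["id"])
    for p in panels[1:]:
        common &= set(p.markers["id"])

    ref = panels[0]
    ref_rows = ref.markers.set_index("id")
    keep_ids: list[str] = []
    dropped: list[str] = []
    flips_per_panel: list[dict[str, bool]] = [dict() for _ in panels]

    allele_maps = [
        dict(zip(p.markers["id"], zip(p.markers["allele_a"],
                                      p.markers["allele_b"])))
        for p in panels
    ]
    for mid in ref.markers["id"]:
        if mid not in common:
            continue
        ra, rb = ref_rows.loc[mid, ["allele_a", "allele_b"]]
        ok = True
        for k, p in enumerate(panels):
            a, b = allele_maps[k][mid]
            if (a, b) == (ra, rb):
                flips_per_panel[k][mid] = False
            elif (a, b) == (rb, ra):
                flips_per_panel[k][mid] = True
            else:
                ok = False
                break
        if ok:
            keep_ids.append(mid)
        else:
            dropped.append(mid)

    if dropped:
        logger.warning(
            "intersect_panels: dropped %d markers with irreconcilable "
            "allele pairs: %s%s", len(dropped), dropped[:5],
            " ..." if len(dropped) > 5 else "")

    keep_set = set(keep_ids)
    n_flipped = 0
    blocks = []
    for k, p in enumerate(panels):
        idx = np.flatnonzero(p.markers["id"].isin(keep_set).to_numpy())
        ids = p.markers["id"].to_numpy()[idx]
        d = p.dosage[:, idx].astype(np.int8).copy()
        flip_cols = np.array([flips_per_panel[k][i] for i in ids], dtype=bool)
        if flip_cols.any():
            n_flipped += int(flip_cols.sum())
            obs = d[:, flip_cols] != MISSING
            d[:, flip_cols] = np.where(obs, 2 - d[:, flip_cols], MISSING)
        blocks.append(pd.DataFrame(d.T, index=ids).T)

    # align columns on the reference marker order
    dosage = np.concatenate(
        [b.loc[:, keep_ids].to_numpy(dtype=np.int8) for b in blocks], axis=0
    )
    markers = ref_rows.loc[keep_ids].reset_index()[MARKER_COLUMNS]
    samples = pd.concat([p.samples for p in panels], ignore_index=True)
    merged = GenotypePanel(markers, samples, dosage)
    report = MergeReport(
        n_markers_common=len(keep_ids),
        n_markers_flipped=n_flipped,
        n_markers_dropped_irreconcilable=len(dropped),
        dropped_ids=dropped,
    )
    return (merged, report) if return_report else merged
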