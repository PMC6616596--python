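"""Per-SNP FST, empirical outlier calling, and selection-region annotation.

FST is estimated per SNP by a one-way analysis of variance on allele
counts across predefined population groups:

    FST = (MSP - MSG) / (MSP + (nC - 1) * MSG)

where MSP and MSG are the between- and within-population mean squares
of gene copies (each copy an observation scored 0/1 for allele b), and
nC is the variance-corrected average number of gene copies per group,
nC = (N - sum_g N_g^2 / N) / (r - 1). Negative estimates are reported
as computed; the empirical outlier rule only concerns the upper tail:
the top 1% of SNPs by FST are flagged as significant, a ±200 kb window
around each flagged SNP is a potential selection region, and regions
are intersected with gene/QTL annotation intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PanelError

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 200_000


@dataclass
class FstResult:
    """Per-SNP FST table, optionally with outlier flags and threshold."""

    table: pd.DataFrame  # marker_id, chromosome, position, fst [, significant]
    threshold: float | None = None
    quantile: float | None = None

    @property
    def significant(self) -> pd.DataFrame:
        if "significant" not in self.table.columns:
            raise PanelError("call_outliers has not been run")
        return self.table[self.table["significant"]]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SelectionRegion:
    chromosome: str
    start: int
    end: int
    snp_id: str
    fst: float


@dataclass
class AnnotationInterval:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    name: str
    kind: str = "gene"


def per_snp_fst(panel: GenotypePanel,
                grouping: dict[str, str] | None = None) -> FstResult:
    """ANOVA-based FST at every SNP across >= 2 groups.

    ``grouping`` maps individual_id -> group label (default: the
    panel's population labels). Groups with no data at a SNP are
    excluded for that SNP; SNPs observed in fewer than 2 groups get
    NaN. SNPs with a zero denominator (no variance at all) get 0.
    """
    if grouping is None:
        labels = panel.samples["population"].to_numpy()
    else:
        labels = panel.samples["individual_id"].map(grouping).to_numpy()
        if pd.isna(labels).any():
            missing = panel.samples["individual_id"][pd.isna(labels)]
            raise PanelError(
                f"grouping lacks labels for {list(missing[:5])} ...")
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) < 2:
        raise PanelError("per_snp_fst needs >= 2 groups")

    d = panel.dosage
    n_snps = panel.n_markers
    # per group: gene-copy counts and allele-b frequencies
    ncopies = np.zeros((len(groups), n_snps))
    pfreq = np.zeros((len(groups), n_snps))
    for gi, g in enumerate(groups):
        rows = np.flatnonzero(labels == g)
        sub = d[rows]
        obs = sub != MISSING
        ng = obs.sum(axis=0)
        ncopies[gi] = 2.0 * ng
        with np.errstate(invalid="ignore", divide="ignore"):
            pfreq[gi] = np.where(ng > 0,
                                 np.where(obs, sub, 0).sum(axis=0) / (2.0 * ng),
                                 np.nan)

    present = ncopies > 0
    r = present.sum(axis=0)
    ncop = np.where(present, ncopies, 0.0)
    pf = np.where(present, pfreq, 0.0)

    n_tot = ncop.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (ncop * pf).sum(axis=0) / n_tot
        ssp = (ncop * (pf - pbar) ** 2).sum(axis=0)
        ssg = (ncop * pf * (1.0 - pf)).sum(axis=0)
        msp = ssp / (r - 1)
        msg = ssg / (n_tot - r)
        nc = (n_tot - (ncop ** 2).sum(axis=0) / n_tot) / (r - 1)
        denom = msp + (nc - 1.0) * msg
        fst = np.where(np.abs(denom) > 0, (msp - msg) / denom, 0.0)
    fst = np.where(r >= 2, fst, np.nan)
    n_skipped = int((r < 2).sum())
    if n_skipped:
        logger.warning("per_snp_fst: %d SNPs observed in < 2 groups "
                       "(fst = NaN)", n_skipped)

    table = pd.DataFrame({
        "marker_id": panel.markers["id"].to_numpy(),
        "chromosome": panel.markers["chromosome"].to_numpy(),
        "position": panel.markers["position"].to_numpy(),
        "fst": fst,
    })
    return FstResult(table=table)


def call_outliers(result: FstResult, quantile: float = 0.99) -> FstResult:
    """Flag the top (1 - quantile) fraction of SNPs by FST.

    Exactly floor((1 - quantile) * M) SNPs are flagged among the M SNPs
    with finite FST, ranked by FST descending; ties at the cut are
    broken deterministically by (chromosome, position). The reported
    threshold is the smallest flagged FST.
    """
    if not 0 < quantile < 1:
        raise PanelError("quantile must be in (0, 1)")
    t = result.table.copy()
    finite = np.isfinite(t["fst"].to_numpy())
    m = int(finite.sum())
    n_flag = int(np.floor((1.0 - quantile) * m))
    order = t[finite].sort_values(
        ["fst", "chromosome", "position"],
        ascending=[False, True, True], kind="stable")
    flagged_idx = order.index[:n_flag]
    t["significant"] = False
    t.loc[flagged_idx, "significant"] = True
    threshold = float(t.loc[flagged_idx, "fst"].min()) if n_flag else np.inf
    return FstResult(table=t, threshold=threshold, quantile=quantile)


def build_regions(result: FstResult,
                  flank_bp: int = DEFAULT_FLANK_BP) -> list[SelectionRegion]:
    """One ±flank region per significant SNP, clipped at position 1.

    Regions are deliberately not merged: the convention is one region
    per outlier SNP.
    """
    regions = [
        SelectionRegion(
            chromosome=str(row.chromosome),
            start=max(1, int(row.position) - flank_bp),
            end=int(row.position) + flank_bp,
            snp_id=str(row.marker_id),
            fst=float(row.fst),
        )
        for row in result.significant.itertuples()
    ]
    return regions


def regions_to_bed(regions: list[SelectionRegion], path) -> None:
    """Write regions as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.snp_id}"
                     f"\t{r.fst:.6g}\n")


def read_annotation_bed(path, kind: str = "gene") -> list[AnnotationInterval]:
    """Read a BED file into 1-based inclusive annotation intervals.

    BED is 0-based half-open; the conversion to the internal convention
    happens here at the boundary.
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PanelError(f"{path}: line {ln}: expected >= 3 "
                                 "tab-separated BED fields")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise PanelError(f"{path}: line {ln}: non-integer "
                                 "coordinates") from exc
            if start0 >= end0:
                raise PanelError(f"{path}: line {ln}: start >= end")
            name = parts[3] if len(parts) > 3 else f"interval_{ln}"
            out.append(AnnotationInterval(
                chromosome=parts[0], start=start0 + 1, end=end0,
                name=name, kind=kind))
    return out


def overlap_annotation(regions: list[SelectionRegion],
                       annotation: list[AnnotationInterval]) -> pd.DataFrame:
    """Closed-interval overlap of selection regions with annotations.

    Two 1-based inclusive intervals overlap when they share at least one
    bp. Returns one row per (region, interval) hit with the region key,
    annotation name and kind; regions without hits are absent.
    """
    if not regions:
        return pd.DataFrame(columns=["chromosome", "start", "end", "snp_id",
                                     "fst", "name", "kind"])
    ann_by_chrom: dict[str, list[AnnotationInterval]] = {}
    for iv in annotation:
        ann_by_chrom.setdefault(iv.chromosome, []).append(iv)
    for lst in ann_by_chrom.values():
        lst.sort(key=lambda iv: (iv.start, iv.end))

    rows = []
    for reg in regions:
        for iv in ann_by_chrom.get(reg.chromosome, []):
            if iv.start > reg.end:
                break
            if iv.end >= reg.start:  # and iv.start <= reg.end
                rows.append((reg.chromosome, reg.start, reg.end, reg.snp_id,
                             reg.fst, iv.name, iv.kind))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                       "snp_id", "fst", "name", "kind"])


def overlap_counts(overlaps: pd.DataFrame) -> pd.DataFrame:
    """Per-annotation counts of regions hit (the 'per-trait' summary)."""
    if overlaps.empty:
        return pd.DataFrame(columns=["name", "kind", "n_regions"])
    g = (overlaps.groupby(["name", "kind"])["snp_id"]
         .nunique().reset_index(name="n_regions"))
    return g.sort_values(["n_regions", "name"],
                         ascending=[False, True]).reset_index(drop=True)
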