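"""Linkage-disequilibrium decay and LD-based historical effective size.

The pipeline here is the package's analytical core:

1. :func:`pairwise_r2` — genotype r² (squared Pearson correlation of
   dosage vectors) for every intra-chromosomal SNP pair within a
   maximum physical distance. Genotype correlations are used because
   phase is typically unknown for SNP-chip panels.
2. :func:`bin_ld` — mean r² in 0.2-Mb distance bins out to 20 Mb
   (100 bins by default).
3. :func:`fit_ld_decay` — least-squares fit of the 4-parameter sigmoid

       E[r²](dist) = (a - d) / (1 + (dist/c)^b) + d

   to the binned means, where a and d are the short- and long-range
   asymptotes, c the half-decay distance and b the decay shape.
4. :func:`ne_trajectory` — historical effective population size from
   the fitted curve via Sved's relation. For generation t the relevant
   recombination frequency is m = 1/(2t); m is converted to map
   distance by inverting m = dist_M * (1 - dist_M / 2) and map distance
   to bp at 1 cM/Mb by default; then

       Ne(t) = 1 / (k * m) * (1 / E[r²] - alpha)

   with k = 4 (Sved's E[r²] = 1/(1 + 4 N c)) and alpha = 1 (the
   classical no-mutation adjustment; alpha = 2 is the mutation-adjusted
   variant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .panel import MISSING, GenotypePanel, PanelError

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_BP = 200_000
DEFAULT_MAX_BP = 20_000_000


@dataclass
class LDPairs:
    """All retained SNP-pair (distance, r²) values plus skip counts."""

    distances_bp: np.ndarray
    r2: np.ndarray
    n_skipped_low_n: int = 0      # fewer than 3 jointly non-missing samples
    n_skipped_monomorphic: int = 0

    def __len__(self) -> int:
        return self.r2.size


@dataclass
class LDBinTable:
    """Mean r² per physical-distance bin.

    Bins tile (0, max_bp] in ``bin_width_bp`` steps; membership is by
    half-open interval (lower, upper], so a pair at exactly 200,000 bp
    falls in bin 1. Empty bins are recorded with pair_count 0 and NaN
    means and are excluded from curve fitting.
    """

    table: pd.DataFrame  # index, lower_bp, upper_bp, mean_distance_bp, mean_r2, pair_count
    bin_width_bp: int
    max_bp: int

    def nonempty(self) -> pd.DataFrame:
        return self.table[self.table["pair_count"] > 0]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class LDDecayFit:
    a: float
    b: float
    c: float
    d: float
    r_squared_of_fit: float
    converged: bool

    def predict(self, distance_bp) -> np.ndarray:
        return predict_r2(self, distance_bp)


# ------------------------------------------------------------- pairs


def _pair_r2_block(x: np.ndarray, obs: np.ndarray,
                   cols_a: np.ndarray, cols_b: np.ndarray,
                   has_missing: bool):
    """r² between all column pairs (a in cols_a) x (b in cols_b).

    Returns (r2 matrix, n_eff matrix) with NaN where undefined.
    ``x`` has missing entries replaced by 0; ``obs`` is the non-missing
    mask as float.
    """
    xa, xb = x[:, cols_a], x[:, cols_b]
    n = x.shape[0]
    if not has_missing:
        mu_a, mu_b = xa.mean(0), xb.mean(0)
        za, zb = xa - mu_a, xb - mu_b
        ssa, ssb = (za ** 2).sum(0), (zb ** 2).sum(0)
        cov = za.T @ zb
        denom = np.outer(ssa, ssb)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(denom > 0, cov ** 2 / denom, np.nan)
        neff = np.full(r2.shape, n)
        return r2, neff

    ma, mb = obs[:, cols_a], obs[:, cols_b]
    nij = ma.T @ mb
    sxy = xa.T @ xb
    sx = xa.T @ mb
    sy = ma.T @ xb
    sxx = (xa ** 2).T @ mb
    syy = ma.T @ (xb ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / nij
        vx = sxx - sx ** 2 / nij
        vy = syy - sy ** 2 / nij
        denom = vx * vy
        r2 = np.where(denom > 0, cov ** 2 / denom, np.nan)
    return r2, nij


def pairwise_r2(panel: GenotypePanel,
                samples: Sequence[int] | None = None,
                max_distance_bp: int = DEFAULT_MAX_BP,
                block: int = 512) -> LDPairs:
    """Genotype r² for all intra-chromosomal SNP pairs within a distance.

    r² is the squared Pearson correlation of the two dosage vectors over
    jointly non-missing samples. Pairs with either marker monomorphic in
    the (jointly observed) subset are skipped, as are pairs with fewer
    than 3 jointly non-missing samples; both skips are counted.
    """
    d = panel.dosage
    if samples is not None:
        d = d[np.asarray(samples), :]
    if d.shape[0] < 2:
        raise PanelError("pairwise_r2 needs >= 2 samples")

    dists_out, r2_out = [], []
    n_low, n_mono = 0, 0

    chroms = panel.markers["chromosome"].to_numpy()
    positions = panel.markers["position"].to_numpy()
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        if cols.size < 2:
            continue
        pos = positions[cols]  # sorted by construction
        sub = d[:, cols]
        obs = (sub != MISSING)
        x = np.where(obs, sub, 0).astype(np.float64)
        obs_f = obs.astype(np.float64)
        has_missing = not obs.all()

        m = cols.size
        for start in range(0, m, block):
            stop = min(start + block, m)
            a_cols = np.arange(start, stop)
            # partners: strictly after each a-column, within max distance
            win_stop = int(np.searchsorted(
                pos, pos[stop - 1] + max_distance_bp, side="right"))
            b_cols = np.arange(start, win_stop)
            if b_cols.size < 2:
                continue
            r2, neff = _pair_r2_block(x, obs_f, a_cols, b_cols, has_missing)
            dd = pos[b_cols][None, :] - pos[a_cols][:, None]
            valid = (dd > 0) & (dd <= max_distance_bp)
            low = valid & (neff < 3)
            n_low += int(low.sum())
            take = valid & ~low
            mono = take & np.isnan(r2)
            n_mono += int(mono.sum())
            take &= ~np.isnan(r2)
            dists_out.append(dd[take])
            r2_out.append(r2[take])

    if not dists_out:
        return LDPairs(np.empty(0, dtype=np.int64), np.empty(0),
                       n_low, n_mono)
    return LDPairs(np.concatenate(dists_out).astype(np.int64),
                   np.concatenate(r2_out), n_low, n_mono)


def bin_ld(pairs: LDPairs,
           bin_width_bp: int = DEFAULT_BIN_WIDTH_BP,
           max_bp: int = DEFAULT_MAX_BP) -> LDBinTable:
    """Average r² in half-open physical-distance bins (lower, upper]."""
    if len(pairs) == 0:
        raise PanelError("bin_ld: no SNP pairs")
    n_bins = int(np.ceil(max_bp / bin_width_bp))
    dist = pairs.distances_bp
    keep = (dist > 0) & (dist <= max_bp)
    dist, r2 = dist[keep], pairs.r2[keep]
    # (lower, upper]: distance exactly on an edge belongs to the lower bin
    idx = np.ceil(dist / bin_width_bp).astype(int) - 1

    count = np.bincount(idx, minlength=n_bins)
    sum_r2 = np.bincount(idx, weights=r2, minlength=n_bins)
    sum_d = np.bincount(idx, weights=dist.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(count > 0, sum_r2 / count, np.nan)
        mean_d = np.where(count > 0, sum_d / count, np.nan)

    table = pd.DataFrame({
        "index": np.arange(1, n_bins + 1),
        "lower_bp": np.arange(n_bins) * bin_width_bp,
        "upper_bp": np.arange(1, n_bins + 1) * bin_width_bp,
        "mean_distance_bp": mean_d,
        "mean_r2": mean_r2,
        "pair_count": count,
    })
    return LDBinTable(table=table, bin_width_bp=bin_width_bp, max_bp=max_bp)


# --------------------------------------------------------------- fit


def _model(params: np.ndarray, dist: np.ndarray) -> np.ndarray:
    a, b, c, d = params
    return (a - d) / (1.0 + (dist / c) ** b) + d


def fit_ld_decay(table: LDBinTable,
                 weight_by_pairs: bool = False) -> LDDecayFit:
    """Fit the 4-parameter decay model to binned mean r².

    Bounded least squares from a deterministic multi-start grid (b in
    {0.5, 1, 2} crossed with log-spaced half-decay distances c); the
    start with the lowest residual wins, earlier starts win ties. Bins
    are unweighted by default; ``weight_by_pairs`` weights residuals by
    sqrt(pair_count).
    """
    nz = table.nonempty()
    if len(nz) < 8:
        raise PanelError(f"fit_ld_decay: only {len(nz)} non-empty bins; "
                         "need >= 8")
    x = nz["mean_distance_bp"].to_numpy(dtype=float)
    y = nz["mean_r2"].to_numpy(dtype=float)
    w = np.sqrt(nz["pair_count"].to_numpy(dtype=float)) if weight_by_pairs \
        else np.ones_like(y)

    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot == 0.0:
        # flat input: the model degenerates to a = d = mean(r2)
        logger.warning("fit_ld_decay: constant bin means; degenerate fit")
        return LDDecayFit(a=float(y[0]), b=1.0, c=float(np.median(x)),
                          d=float(y[0]), r_squared_of_fit=0.0,
                          converged=True)

    lo = np.array([0.0, 1e-3, 1.0, 0.0])
    hi = np.array([1.0, 20.0, 1e10, 1.0])
    a0, d0 = float(y.max()), float(y.min())

    def resid(p):
        return w * (_model(p, x) - y)

    best = None
    c_grid = np.geomspace(max(x.min(), 1.0), x.max(), 3)
    for b0 in (0.5, 1.0, 2.0):
        for c0 in c_grid:
            p0 = np.clip(np.array([a0, b0, c0, d0]), lo + 1e-12, hi - 1e-12)
            try:
                res = least_squares(resid, p0, bounds=(lo, hi),
                                    method="trf", max_nfev=2000)
            except Exception:       # numerical failure of one start
                continue
            if res.status > 0 and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        raise PanelError("fit_ld_decay: no start converged")

    a, b, c, d = best.x
    if a < d:
        # the sigmoid is symmetric under (a<->d, b->-b); with b bounded
        # positive an increasing fit can only arise from noise — keep it
        # but flag via the fit R²
        logger.warning("fit_ld_decay: fitted a < d (increasing curve)")
    ssres = float((resid(best.x) ** 2).sum()) if not weight_by_pairs else \
        float(((_model(best.x, x) - y) ** 2).sum())
    r2fit = 1.0 - ssres / sstot
    return LDDecayFit(a=float(a), b=float(b), c=float(c), d=float(d),
                      r_squared_of_fit=r2fit, converged=True)


def predict_r2(fit: LDDecayFit, distance_bp) -> np.ndarray | float:
    """Model-predicted r² at a physical distance, clamped to [0, 1]."""
    if not fit.converged:
        raise PanelError("predict_r2: fit did not converge")
    dist = np.asarray(distance_bp, dtype=float)
    if np.any(dist <= 0):
        raise PanelError("predict_r2: distance must be positive")
    out = np.clip(_model((fit.a, fit.b, fit.c, fit.d), dist), 0.0, 1.0)
    return float(out) if np.isscalar(distance_bp) else out


# ---------------------------------------------------------- Sved Ne


def ne_trajectory(fit: LDDecayFit | Callable[[float], float],
                  t_min: int = 3, t_max: int = 100,
                  k: float = 4.0, alpha: float = 1.0,
                  morgans_per_bp: float = 1e-8) -> pd.DataFrame:
    """Historical Ne for generations t_min..t_max from a fitted LD curve.

    For each generation t: recombination frequency m = 1/(2t); map
    distance from Haldane-style inversion dist_M = 1 - sqrt(1 - 2m)
    (the root of m = dist_M (1 - dist_M/2) in [0, 1]); physical distance
    dist_M / morgans_per_bp (default 1 Morgan = 100 Mb); expected r²
    from the fitted decay curve at that distance; and

        Ne(t) = 1/(k m) * (1/E[r²] - alpha).

    ``fit`` may also be any callable mapping distance in bp to r², which
    makes the mapping invertible in closed form for testing. Rows where
    E[r²] <= 0 or 1/E[r²] <= alpha are flagged invalid (``valid`` column
    False, Ne NaN), never silently dropped.
    """
    if t_min < 1 or t_max < t_min:
        raise PanelError("ne_trajectory: need 1 <= t_min <= t_max")
    predictor = fit if callable(fit) and not isinstance(fit, LDDecayFit) \
        else (lambda bp: predict_r2(fit, bp))

    rows = []
    for t in range(t_min, t_max + 1):
        m = 1.0 / (2.0 * t)
        dist_m = 1.0 - np.sqrt(1.0 - 2.0 * m)
        dist_bp = dist_m / morgans_per_bp
        r2 = float(predictor(dist_bp))
        valid = r2 > 0 and (1.0 / r2 - alpha) > 0
        ne = (1.0 / (k * m)) * (1.0 / r2 - alpha) if valid else np.nan
        rows.append((t, m, dist_bp, r2, ne, valid))
        if not valid:
            logger.warning("ne_trajectory: t=%d invalid (E[r2]=%.4g, "
                           "alpha=%.3g)", t, r2, alpha)
    return pd.DataFrame(
        rows, columns=["t", "m", "distance_bp", "predicted_r2", "ne",
                       "valid"])
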