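"""Principal component analysis of genotypes via a genomic relationship matrix.

The GRM entry for individuals j and k is

    G_jk = (1/M) * sum_m (x_jm - 2 p_m)(x_km - 2 p_m) / (2 p_m (1 - p_m))

with x the allele-b dosage and p_m the pooled allele-b frequency —
i.e. the average cross-product of per-marker standardized genotypes.
Missing dosages are mean-imputed per marker; monomorphic markers carry
no information and are skipped. PCA is the eigendecomposition of G:
coordinates are eigenvectors scaled by sqrt(eigenvalue) and the
variance contribution of component k is its eigenvalue's share of the
positive-eigenvalue total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PanelError

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    coordinates: np.ndarray    # (n_samples, K)
    contributions: np.ndarray  # (K,) eigenvalue shares of the positive total
    eigenvalues: np.ndarray    # (K,) descending

    def to_frame(self, samples: pd.DataFrame | None = None) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(self.coordinates,
                          columns=[f"pc{i + 1}" for i in range(k)])
        if samples is not None:
            df.insert(0, "population", samples["population"].to_numpy())
            df.insert(0, "individual_id", samples["individual_id"].to_numpy())
        return df


def grm(panel: GenotypePanel, markers=None,
        standardize: bool = True) -> np.ndarray:
    """Genomic relationship matrix over a marker subset.

    ``standardize=False`` switches to a plain covariance matrix of
    mean-centred dosages (no per-marker variance scaling).
    """
    d = panel.dosage
    if markers is not None:
        d = d[:, np.asarray(markers)]
    x = d.astype(np.float64)
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        raise PanelError("grm: marker with all genotypes missing")
    p = np.where(obs, x, 0).sum(axis=0) / (2.0 * n_obs)

    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.warning("grm: skipping %d monomorphic markers", n_mono)
    if not poly.any():
        raise PanelError("grm: no polymorphic markers in subset")
    x, p = x[:, poly], p[poly]
    obs = obs[:, poly]

    x = np.where(obs, x, 2.0 * p)          # mean-impute missing
    z = x - 2.0 * p
    if standardize:
        z = z / np.sqrt(2.0 * p * (1.0 - p))
    m = z.shape[1]
    return (z @ z.T) / m


def pca_from_grm(g: np.ndarray, k: int = 10) -> PcaResult:
    """Top-K principal components of a relationship matrix.

    ``k`` is truncated (with a warning) to the number of strictly
    positive eigenvalues. Eigenvector signs are arbitrary.
    """
    g = np.asarray(g, dtype=float)
    if g.shape[0] != g.shape[1] or not np.allclose(g, g.T, atol=1e-8):
        raise PanelError("pca_from_grm: matrix must be symmetric")
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    pos = vals > max(1e-12, 1e-12 * abs(vals[0]))
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise PanelError("pca_from_grm: no positive eigenvalues")
    if k > n_pos:
        logger.warning("pca_from_grm: K=%d exceeds %d positive eigenvalues; "
                       "truncating", k, n_pos)
        k = n_pos
    lam = vals[:k]
    coords = vecs[:, :k] * np.sqrt(lam)[None, :]
    contrib = lam / vals[pos].sum()
    return PcaResult(coordinates=coords, contributions=contrib,
                     eigenvalues=lam)


def pca(panel: GenotypePanel, markers=None, k: int = 10,
        standardize: bool = True) -> PcaResult:
    """Convenience wrapper: GRM then eigendecomposition."""
    return pca_from_grm(grm(panel, markers, standardize=standardize), k=k)
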