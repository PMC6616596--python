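"""Genetic distances and neighbor-joining trees.

Two distances are provided: an individual-level allele-sharing distance
D = 1 - (IBS2 + 0.5*IBS1)/N, where IBS2 and IBS1 count loci at which a
pair of individuals shares two or exactly one allele identical by
state, and Nei's standardized genetic distance between populations,

    Dxy = -ln[ J_xy / sqrt(J_x * J_y) ]

with J_xy = sum over loci and alleles of x_ij * y_ij (the allelic
identity coefficients). Trees are built by the classic Saitou-Nei
neighbor-joining agglomeration and serialized as newick.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PanelError

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise PanelError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise PanelError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise PanelError("distance matrix diagonal must be zero")
        finite = self.values[np.isfinite(self.values)]
        if (finite < 0).any():
            raise PanelError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


# --------------------------------------------------------------- trees


@dataclass
class TreeNode:
    """Node of an (unrooted, stored-rooted) phylogenetic tree."""

    label: str | None = None
    length: float = 0.0  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label] if self.label is not None else []
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


_NEWICK_META = set("(),:;'\" \t\n[]")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_META for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class PhyloTree:
    """Unrooted tree produced by neighbor joining.

    Stored with an arbitrary trifurcating root (the final NJ join); leaf
    labels match the input distance-matrix labels exactly.
    """

    root: TreeNode

    def leaf_labels(self) -> list[str]:
        return self.root.leaves()

    def total_length(self) -> float:
        def rec(node: TreeNode) -> float:
            return node.length + sum(rec(c) for c in node.children)
        return rec(self.root) - self.root.length

    def to_newick(self) -> str:
        def rec(node: TreeNode) -> str:
            if not node.children:
                return f"{_quote(node.label)}:{node.length:.10g}"
            inner = ",".join(rec(c) for c in node.children)
            return f"({inner}):{node.length:.10g}"
        inner = ",".join(rec(c) for c in self.root.children)
        return f"({inner});"


def write_newick(tree: PhyloTree, path) -> None:
    """Serialize a tree as a one-line newick file."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ------------------------------------------------------ IBS distance


def ibs_distance(panel: GenotypePanel,
                 sample_idx=None) -> DistanceMatrix:
    """Allele-sharing distance between all pairs of individuals.

    For each pair, loci missing in either individual are excluded; over
    the remaining N loci D = 1 - (IBS2 + 0.5*IBS1)/N. D is 0 for
    identical genotype vectors and 1 for opposite homozygotes at every
    locus.
    """
    d = panel.dosage
    samples = panel.samples
    if sample_idx is not None:
        sample_idx = np.asarray(sample_idx)
        d = d[sample_idx]
        samples = samples.iloc[sample_idx]
    n = d.shape[0]
    if n < 2:
        raise PanelError("ibs_distance needs >= 2 samples")

    x = d.astype(np.float64)
    obs = d != MISSING
    x[~obs] = np.nan

    # |dosage_i - dosage_j| = 0 -> IBS2, 1 -> IBS1, 2 -> IBS0; so the
    # per-locus shared fraction is 1 - |di - dj| / 2 and D reduces to
    # mean(|di - dj|) / 2 over jointly observed loci.
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i][None, :] - x[i + 1:])         # (n-i-1, m)
        cnt = np.sum(~np.isnan(diff), axis=1)
        if (cnt == 0).any():
            j = i + 1 + int(np.flatnonzero(cnt == 0)[0])
            raise PanelError(
                f"ibs_distance: samples "
                f"{samples['individual_id'].iloc[i]!r} and "
                f"{samples['individual_id'].iloc[j]!r} share no "
                "non-missing loci")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            row = np.nanmean(diff, axis=1) / 2.0
        out[i, i + 1:] = row
        out[i + 1:, i] = row
    return DistanceMatrix(samples["individual_id"].tolist(), out)


# ------------------------------------------------------ Nei distance


def nei_distance(panel: GenotypePanel,
                 grouping: dict[str, str] | None = None) -> DistanceMatrix:
    """Nei's standardized genetic distance between populations.

    ``grouping`` optionally maps individual_id -> group label; by default
    the panel's population labels are used. Loci with no data in either
    population of a pair are excluded for that pair. A pair of
    populations fixed for disjoint alleles at some locus has identity
    coefficient 0 and distance +inf (reported with a warning).
    """
    if grouping is None:
        labels = panel.samples["population"].to_numpy()
    else:
        labels = panel.samples["individual_id"].map(grouping).to_numpy()
    pops = sorted(pd.unique(labels).tolist())
    if len(pops) < 2:
        raise PanelError("nei_distance needs >= 2 populations")

    freqs = {}
    for pop in pops:
        idx = np.flatnonzero(labels == pop)
        if idx.size == 0:
            raise PanelError(f"population {pop!r} has no samples")
        freqs[pop] = panel.allele_b_frequencies(sample_idx=idx)

    k = len(pops)
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            x, y = freqs[pops[a]], freqs[pops[b]]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if not ok.any():
                raise PanelError(
                    f"nei_distance: {pops[a]} and {pops[b]} share no typed "
                    "loci")
            xa, ya = x[ok], y[ok]
            jxy = np.sum(xa * ya + (1 - xa) * (1 - ya))
            jx = np.sum(xa ** 2 + (1 - xa) ** 2)
            jy = np.sum(ya ** 2 + (1 - ya) ** 2)
            ident = jxy / np.sqrt(jx * jy)
            if ident <= 0:
                logger.warning("nei_distance: %s vs %s identity <= 0; "
                               "distance reported as +inf", pops[a], pops[b])
                dist = np.inf
            else:
                # clip tiny floating excess above 1 (identical frequencies)
                dist = -np.log(min(ident, 1.0))
            out[a, b] = out[b, a] = dist
    return DistanceMatrix(pops, out)


# -------------------------------------------------- neighbor joining


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q-criterion is joined at each step; ties are
    broken by the lowest (row, column) index pair. Negative estimated
    branch lengths are clamped to zero. NJ is consistent: on an additive
    distance matrix the generating topology and branch lengths are
    recovered exactly.
    """
    labels = list(dist.labels)
    n = len(labels)
    if n < 3:
        raise PanelError("neighbor_joining needs >= 3 taxa")
    d = np.array(dist.values, dtype=float)
    if not np.all(np.isfinite(d)):
        raise PanelError("neighbor_joining: non-finite distances")

    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) among minima, j > i for determinism
        iu = np.triu_indices(m, k=1)
        qmin = q[iu].min()
        flat = np.flatnonzero(np.isclose(q[iu], qmin, rtol=0, atol=0))
        i_loc, j_loc = iu[0][flat[0]], iu[1][flat[0]]

        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.children = [nodes[i], nodes[j]]

        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0])
        for k_loc, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.vstack([d, new_row[None, :]])
        new_col = np.append(new_row, 0.0)
        d = np.hstack([d, new_col[:, None]])
        nodes.append(parent)
        new_index = d.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [new_index]

    # final trifurcation: closed-form branch lengths for 3 nodes
    a, b, c = active
    va = max(0.5 * (d[a, b] + d[a, c] - d[b, c]), 0.0)
    vb = max(0.5 * (d[a, b] + d[b, c] - d[a, c]), 0.0)
    vc = max(0.5 * (d[a, c] + d[b, c] - d[a, b]), 0.0)
    nodes[a].length, nodes[b].length, nodes[c].length = va, vb, vc
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    tree = PhyloTree(root=root)
    assert sorted(tree.leaf_labels()) == sorted(labels)
    return tree
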