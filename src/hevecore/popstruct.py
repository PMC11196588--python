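"""Genetic distances, neighbor-joining trees, group assignment and PCA.

The pairwise distance is 1 minus the identity-by-state (IBS) proportion:
at each locus called in both samples a pair of diploid genotypes shares
(2 - |g_i - g_j|)/2 of its alleles by state, and the distance averages
this over shared loci.  Trees are built with the classical Saitou–Nei
neighbor-joining algorithm, which is exact on additive matrices; group
assignment cuts the longest internal branches of the midpoint-rooted
tree.  PCA standardizes each genotype column as (g - 2p)/sqrt(2p(1-p))
(the usual variance standardization for SNP data) with missing entries
set to zero after centering.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .errors import DegenerateTreeWarning, ZeroSharedLociError
from .genotype_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with the shared-locus count per pair."""

    ids: list[str]
    values: np.ndarray
    n_shared: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids], dtype=int)
        return DistanceMatrix(
            list(ids),
            self.values[np.ix_(idx, idx)],
            None if self.n_shared is None else self.n_shared[np.ix_(idx, idx)],
        )


def ibs_distance(panel: GenotypePanel) -> DistanceMatrix:
    """1 - IBS proportion over loci called in both members of each pair."""
    if panel.n_samples < 2:
        raise ValueError("need at least two samples")
    G = panel.G.astype(np.int16)
    called = G != MISSING
    n = panel.n_samples
    dist = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        both = called[i] & called[i + 1 :]
        n_shared = both.sum(axis=1)
        if np.any(n_shared == 0):
            j = i + 1 + int(np.argmax(n_shared == 0))
            raise ZeroSharedLociError(
                f"samples {panel.sample_ids[i]} and {panel.sample_ids[j]} "
                "share no called loci"
            )
        sim = np.where(both, (2 - np.abs(G[i] - G[i + 1 :])) / 2.0, 0.0).sum(axis=1)
        d = 1.0 - sim / n_shared
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
        shared[i, i + 1 :] = n_shared
        shared[i + 1 :, i] = n_shared
    np.fill_diagonal(shared, panel.called_mask().sum(axis=1))
    # clip tiny negatives from floating-point roundoff
    np.clip(dist, 0.0, None, out=dist)
    return DistanceMatrix(list(panel.sample_ids), dist, shared)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical Saitou–Nei neighbor joining.

    At each step the pair minimizing
    ``Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)``
    is joined; ties are broken by the smallest (row, column) index pair in
    the current node order (original sample order, new nodes appended).
    The result is returned as an unrooted tree represented with a
    trifurcating root.  Branch lengths may be negative on non-additive
    inputs; they are preserved here and clamped only at Newick export.
    """
    n0 = dm.n
    if n0 < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    size = 2 * n0
    M = np.zeros((size, size))
    M[:n0, :n0] = dm.values
    nodes: list[TreeNode] = [TreeNode(name=s) for s in dm.ids]
    active = list(range(n0))
    next_free = n0

    while len(active) > 3:
        idx = np.array(active)
        sub = M[np.ix_(idx, idx)]
        r = len(idx)
        sums = sub.sum(axis=1)
        Q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        a, b = divmod(int(np.argmin(Q)), r)  # row-major argmin => smallest (a, b)
        d_ab = sub[a, b]
        la = 0.5 * d_ab + (sums[a] - sums[b]) / (2.0 * (r - 2))
        lb = d_ab - la
        child_a, child_b = nodes[idx[a]], nodes[idx[b]]
        child_a.length = float(la)
        child_b.length = float(lb)
        parent = TreeNode(children=[child_a, child_b])
        nodes.append(parent)
        u = next_free
        next_free += 1
        for k in active:
            if k == idx[a] or k == idx[b]:
                continue
            d = 0.5 * (M[idx[a], k] + M[idx[b], k] - d_ab)
            M[u, k] = M[k, u] = d
        active = [k for k in active if k not in (idx[a], idx[b])] + [u]

    x, y, z = active
    dxy, dxz, dyz = M[x, y], M[x, z], M[y, z]
    nodes[x].length = float((dxy + dxz - dyz) / 2.0)
    nodes[y].length = float((dxy + dyz - dxz) / 2.0)
    nodes[z].length = float((dxz + dyz - dxy) / 2.0)
    root = TreeNode(children=[nodes[x], nodes[y], nodes[z]])
    root.length = None
    return root


def to_newick(tree: TreeNode) -> str:
    """Serialize to Newick; negative branch lengths are clamped to zero."""
    out = tree.copy()
    n_clamped = 0
    for node in out.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.info("clamped %d negative branch lengths to 0 at export", n_clamped)
    buf = io.StringIO()
    out.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(newick: str) -> TreeNode:
    """Parse a Newick string.

    Follows the Newick conventions skbio implements: unquoted underscores
    decode to spaces (the writer encodes spaces as underscores), and names
    with other special characters are quoted.
    """
    return TreeNode.read(io.StringIO(newick), format="newick")


def assign_groups(tree: TreeNode, k: int = 2) -> dict[str, int]:
    """Partition leaves into ``k`` groups by cutting internal branches.

    ``k - 1`` internal branches of the midpoint-rooted tree are cut
    greedily, each cut chosen to minimize the Ward-style within-group
    dispersion ``sum_g (within-group cophenetic distance sum) / n_g`` of
    the resulting partition — the tree-constrained analogue of minimum
    within-cluster dispersion.  This is robust to long terminal "cherry"
    branches that carry no group signal, unlike a longest-branch cut,
    and to the size imbalance of germplasm groups, unlike an
    unnormalized distance sum.  Ties break by traversal index,
    so the assignment is deterministic.  Labels are integers numbered by
    first appearance in tip order.  A tree whose branches are all
    zero-length triggers a :class:`DegenerateTreeWarning` and a single
    group.
    """
    tips = [t.name for t in tree.tips()]
    n = len(tips)
    if k < 1 or k > n:
        raise ValueError("k must lie in [1, n_leaves]")
    if k == 1:
        return {t: 0 for t in tips}
    total_length = sum(nd.length or 0.0 for nd in tree.traverse() if nd.length)
    if total_length == 0:
        warnings.warn(
            "all branch lengths are zero; returning a single group",
            DegenerateTreeWarning,
            stacklevel=2,
        )
        return {t: 0 for t in tips}
    if k == n:
        return {t: i for i, t in enumerate(tips)}
    rooted = tree.copy().root_at_midpoint()
    dm = rooted.tip_tip_distances()
    tip_order = list(dm.ids)
    tip_pos = {name: i for i, name in enumerate(tip_order)}
    D = dm.data

    internal = [
        nd for nd in rooted.preorder(include_self=False) if not nd.is_tip()
    ]
    if len(internal) < k - 1:
        raise ValueError(
            f"tree has only {len(internal)} internal branches; cannot cut {k - 1}"
        )
    # membership vector of the tip set below each internal edge
    membership = {}
    for i, nd in enumerate(internal):
        m = np.zeros(n, dtype=bool)
        for t in nd.tips():
            m[tip_pos[t.name]] = True
        membership[i] = m

    def within_sum(labels: np.ndarray) -> float:
        total = 0.0
        for g in np.unique(labels):
            m = labels == g
            total += float(D[np.ix_(m, m)].sum()) / (2.0 * int(m.sum()))
        return total

    labels = np.zeros(n, dtype=int)
    cut_set: list[int] = []
    for _ in range(k - 1):
        best = None
        for i in range(len(internal)):
            if i in cut_set:
                continue
            trial = _partition_labels(n, [membership[j] for j in cut_set + [i]])
            score = within_sum(trial)
            if best is None or score < best[0] - 1e-12:
                best = (score, i, trial)
        if best is None:
            break
        cut_set.append(best[1])
        labels = best[2]

    # renumber by first appearance in the caller-visible tip order
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for name in tips:
        g = int(labels[tip_pos[name]])
        if g not in remap:
            remap[g] = len(remap)
        out[name] = remap[g]
    return out


def _partition_labels(n: int, memberships: list[np.ndarray]) -> np.ndarray:
    """Labels induced by cutting the edges whose below-edge tip sets are given.

    The tip sets form a laminar family; a tip's group is determined by the
    smallest cut set containing it (its nearest cut ancestor edge), or the
    root component if none contains it.
    """
    labels = np.full(n, -1, dtype=int)
    # sort by set size ascending so the smallest containing set wins
    for gid, m in enumerate(sorted(memberships, key=lambda m: int(m.sum()))):
        labels[(labels == -1) & m] = gid
    labels[labels == -1] = len(memberships)
    return labels


@dataclass
class PCAResult:
    """Sample coordinates and explained-variance percentages."""

    sample_ids: list[str]
    coordinates: np.ndarray
    explained_pct: np.ndarray
    loci_used: list[str]


def pca(panel: GenotypePanel, n_components: int = 10) -> PCAResult:
    """Variance-standardized genotype PCA.

    Each polymorphic locus column is transformed to
    ``(g - 2p) / sqrt(2p(1 - p))`` with ``p`` the alternate-allele
    frequency over called genotypes; missing entries become 0 after
    centering; monomorphic loci are dropped.  Coordinates are
    eigenvectors of the sample covariance scaled by the square root of
    their eigenvalues; explained percentages are eigenvalue shares.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least two samples")
    G = panel.G.astype(float)
    called = G != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, G, 0.0).sum(axis=0) / (2.0 * n_called)
    poly = (n_called > 0) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic loci")
    Gp = G[:, poly]
    pp = p[poly]
    X = (Gp - 2.0 * pp) / np.sqrt(2.0 * pp * (1.0 - pp))
    X[~called[:, poly]] = 0.0
    cov = X @ X.T / X.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    c = min(n_components, len(eigval))
    coords = eigvec[:, :c] * np.sqrt(eigval[:c])
    total = eigval.sum()
    explained = 100.0 * eigval[:c] / total if total > 0 else np.zeros(c)
    loci_used = [panel.locus_ids[j] for j in np.flatnonzero(poly)]
    return PCAResult(list(panel.sample_ids), coords, explained, loci_used)
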