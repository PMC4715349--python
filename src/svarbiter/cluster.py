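"""Hierarchical clustering of transformed annotation vectors.

Sites are clustered with Manhattan (L1) distance — less influenced by
single-annotation outliers than Euclidean — and Ward's agglomeration
applied directly to the L1 dissimilarities (the classic ``ward.D``
convention: the Lance–Williams update is run on the provided
dissimilarities without squaring them first).  That pairing is formally
heterodox, since Ward's variance argument assumes squared Euclidean
distances, but it is the established behaviour of R's ``hclust`` and
separates SV types from random regions well in practice; we therefore keep
it and implement the agglomeration loop by hand (scipy's ``ward`` linkage
is the D2 convention).  The result is returned in scipy's linkage-matrix
layout so standard dendrogram/tree tooling applies.

Classical (Torgerson) multidimensional scaling embeds the distance matrix
in a few dimensions for visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import AnnotationTable

__all__ = [
    "ClusteringResult",
    "l1_distance_matrix",
    "ward_cluster",
    "leaf_order",
    "cut_tree",
    "mds_embedding",
    "cluster_composition",
]


def l1_distance_matrix(table: AnnotationTable | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Site x site Manhattan distances d(i,j) = sum_a |z_ia - z_ja|."""
    if isinstance(table, AnnotationTable):
        x = table.values.to_numpy()
    else:
        x = np.asarray(table, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError(
            "non-finite values in annotation matrix; impute masked cells first "
            "(apply_transform does this)"
        )
    return squareform(pdist(x, metric="cityblock"))


def ward_cluster(distances: np.ndarray) -> np.ndarray:
    """Ward-style agglomeration on raw dissimilarities (ward.D convention).

    Returns a scipy-format linkage matrix: row t = [id_a, id_b, height,
    size] where ids < n are leaves and id n+t is the cluster formed at step
    t.  Heights are the Lance–Williams-updated dissimilarities at each
    merge; Ward's update is reducible, so greedy nearest-pair merging
    yields non-decreasing heights.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 2:
        raise ValueError("need a square distance matrix with n >= 2")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    work = d.copy()
    np.fill_diagonal(work, np.inf)
    sizes = {i: 1 for i in range(n)}
    ids = list(range(n))          # cluster id per active row
    active = list(range(n))       # active row indices into `work`
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        sub = work[np.ix_(active, active)]
        flat = np.argmin(sub)
        ai, aj = np.unravel_index(flat, sub.shape)
        if ai > aj:
            ai, aj = aj, ai
        ri, rj = active[ai], active[aj]
        h = work[ri, rj]
        id_i, id_j = ids[ri], ids[rj]
        ni, nj = sizes[id_i], sizes[id_j]
        # Lance-Williams Ward update on the raw dissimilarities
        for rk in active:
            if rk in (ri, rj):
                continue
            nk = sizes[ids[rk]]
            new = ((ni + nk) * work[ri, rk] + (nj + nk) * work[rj, rk] - nk * h) / (
                ni + nj + nk
            )
            work[ri, rk] = work[rk, ri] = new
        lo, hi = sorted((id_i, id_j))
        Z[step] = [lo, hi, h, ni + nj]
        sizes[next_id] = ni + nj
        ids[ri] = next_id
        next_id += 1
        active.remove(rj)
    return Z


def _children(Z: np.ndarray, n: int) -> dict[int, tuple[int, int]]:
    return {n + t: (int(Z[t, 0]), int(Z[t, 1])) for t in range(len(Z))}


def _node_height(node: int, Z: np.ndarray, n: int) -> float:
    return 0.0 if node < n else float(Z[node - n, 2])


def _min_leaf(node: int, Z: np.ndarray, n: int, memo: dict[int, int]) -> int:
    if node < n:
        return node
    if node not in memo:
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        memo[node] = min(_min_leaf(a, Z, n, memo), _min_leaf(b, Z, n, memo))
    return memo[node]


def leaf_order(Z: np.ndarray) -> list[int]:
    """Dendrogram leaf order: the tighter (lower-height) subtree goes left;
    ties break to the subtree containing the smallest leaf index."""
    n = len(Z) + 1
    memo: dict[int, int] = {}
    order: list[int] = []

    def visit(node: int) -> None:
        if node < n:
            order.append(node)
            return
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        ka = (_node_height(a, Z, n), _min_leaf(a, Z, n, memo))
        kb = (_node_height(b, Z, n), _min_leaf(b, Z, n, memo))
        first, second = (a, b) if ka <= kb else (b, a)
        visit(first)
        visit(second)

    visit(2 * n - 2)
    return order


def cut_tree(
    Z: np.ndarray,
    height: float | None = None,
    n_clusters: int | None = None,
) -> np.ndarray:
    """Cut the merge tree at a height or to a cluster count.

    Exactly one of ``height``/``n_clusters`` must be given.  Labels are
    integers 1..k numbered left-to-right in dendrogram order.
    """
    if (height is None) == (n_clusters is None):
        raise ValueError("give exactly one of height or n_clusters")
    n = len(Z) + 1
    if n_clusters is not None:
        if not (1 <= n_clusters <= n):
            raise ValueError(f"n_clusters must be in [1, {n}]")
        n_merges = n - n_clusters
    else:
        n_merges = int(np.sum(Z[:, 2] <= height))
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n_merges):
        a, b = int(Z[t, 0]), int(Z[t, 1])
        node = n + t
        parent[find(a)] = node
        parent[find(b)] = node
    roots = [find(i) for i in range(n)]
    label_of_root: dict[int, int] = {}
    labels = np.zeros(n, dtype=int)
    for leaf in leaf_order(Z):
        r = roots[leaf]
        if r not in label_of_root:
            label_of_root[r] = len(label_of_root) + 1
        labels[leaf] = label_of_root[r]
    return labels


def mds_embedding(distances: np.ndarray, k: int = 3) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix into k dimensions.

    Double-centres the squared distances, eigendecomposes, and returns the
    top-k coordinates ordered by decreasing eigenvalue (negative
    eigenvalues contribute zero coordinates).  Sign convention: the first
    nonzero loading of each dimension is positive.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if not (0 < k < n):
        raise ValueError("require 0 < k < n")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    lam[lam < lam.max() * 1e-12] = 0.0  # rounding-level modes carry no geometry
    coords = vecs[:, idx] * np.sqrt(lam)
    for dim in range(k):
        col = coords[:, dim]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, dim] = -col
    return coords


def cluster_composition(
    labels: Sequence[int],
    sources: Sequence[str],
    sv_sources: set[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster counts by source call set, plus the SV proportion.

    ``sv_sources`` names the call sets regarded as SVs; when omitted,
    sources other than random/repeat-element samples count as SVs.
    """
    labels = np.asarray(labels)
    sources = np.asarray(sources, dtype=object)
    if labels.shape != sources.shape:
        raise ValueError("labels and sources must align")
    df = pd.DataFrame({"cluster": labels, "source": sources})
    counts = df.groupby(["cluster", "source"]).size().unstack(fill_value=0)
    counts["total"] = counts.sum(axis=1)
    if sv_sources is None:
        non_sv_prefixes = ("random", "SINE", "LINE", "LTR", "low_complexity", "simple_repeat")
        sv_sources = {
            s for s in set(sources) if not str(s).startswith(non_sv_prefixes)
        }
    sv_cols = [c for c in counts.columns if c in sv_sources]
    counts["prop_sv"] = counts[sv_cols].sum(axis=1) / counts["total"]
    return counts


@dataclass
class ClusteringResult:
    """Merge tree, labels at a cut, MDS coordinates and composition table."""

    linkage: np.ndarray
    labels: np.ndarray
    mds: np.ndarray
    composition: pd.DataFrame
    site_ids: list[str] = field(default_factory=list)


def run_clustering(
    table: AnnotationTable,
    sources: Sequence[str],
    n_clusters: int | None = None,
    height: float | None = None,
    mds_dims: int = 3,
    sv_sources: set[str] | None = None,
) -> ClusteringResult:
    """Distance matrix -> Ward tree -> cut -> MDS -> composition, in one call."""
    d = l1_distance_matrix(table)
    Z = ward_cluster(d)
    labels = cut_tree(Z, height=height, n_clusters=n_clusters)
    coords = mds_embedding(d, k=min(mds_dims, len(d) - 1))
    comp = cluster_composition(labels, sources, sv_sources)
    return ClusteringResult(Z, labels, coords, comp, table.site_ids)
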