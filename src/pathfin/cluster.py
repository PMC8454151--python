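"""Agglomerative hierarchical clustering of drugs from similarity matrices.

The linkage is implemented here (complete/average/single, with a
deterministic lexicographic tie-break) and emits a scipy-style merge
table, so flat cuts and tree export can reuse ``scipy.cluster.hierarchy``.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch

from .similarity import SimilarityMatrix

__all__ = [
    "Dendrogram",
    "similarity_to_distance",
    "hierarchical_cluster",
    "cut_clusters",
    "rank_references",
]

_LINKAGES = ("complete", "average", "single")


def similarity_to_distance(matrix: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Convert a bounded similarity matrix to a distance matrix via d = 1 - s."""
    values = matrix.values if isinstance(matrix, SimilarityMatrix) else np.asarray(matrix, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValueError("similarity matrix is asymmetric beyond 1e-9")
    if np.nanmin(values) < -1e-12 or np.nanmax(values) > 1 + 1e-12:
        raise ValueError("similarity values must lie in [0, 1]")
    d = 1.0 - values
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, None)


@dataclass(frozen=True)
class Dendrogram:
    """Merge history of an agglomerative clustering.

    ``merges`` is a scipy-format linkage matrix: row i merges clusters
    ``merges[i, 0]`` and ``merges[i, 1]`` (leaves are 0..n-1, the merge
    result gets id n+i) at height ``merges[i, 2]`` into a cluster of size
    ``merges[i, 3]``.
    """

    labels: tuple[str, ...]
    merges: np.ndarray
    linkage: str
    distance: str = "1 - similarity"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[str]:
        order = sch.leaves_list(self.merges)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        rep = {i: i for i in range(n)}  # children ordered by smallest leaf
        for i, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            if rep[b] < rep[a]:
                a, b = b, a
            la = h - height[a]
            lb = h - height[b]
            node[n + i] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + i] = float(h)
            rep[n + i] = min(rep[a], rep[b])
        root = n + len(self.merges) - 1 if len(self.merges) else 0
        return node[root] + ";"


def _merge_distance(
    method: str, d_ak: float, d_bk: float, size_a: int, size_b: int
) -> float:
    if method == "complete":
        return max(d_ak, d_bk)
    if method == "single":
        return min(d_ak, d_bk)
    # average (UPGMA): size-weighted mean, matches scipy
    return (size_a * d_ak + size_b * d_bk) / (size_a + size_b)


def hierarchical_cluster(
    distances: np.ndarray,
    labels: Sequence[str] | None = None,
    linkage: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering of a full distance matrix.

    Ties in merge order are broken by the lexicographically smallest pair
    of cluster representatives (smallest contained leaf index), making the
    result deterministic across platforms.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if labels is None:
        labels = [str(i) for i in range(n)]
    elif len(labels) != n:
        raise ValueError("labels length does not match matrix size")

    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    rep = {i: i for i in range(n)}  # smallest leaf in each active cluster
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], *sorted((rep[kv[0][0]], rep[kv[0][1]]))),
        )
        (a, b), h = best
        new = n + step
        merges[step] = (a, b, h, size[a] + size[b])
        rep[new] = min(rep[a], rep[b])
        size[new] = size[a] + size[b]
        active -= {a, b}
        for k in sorted(active):
            d_ak = dist.pop((min(a, k), max(a, k)))
            d_bk = dist.pop((min(b, k), max(b, k)))
            dist[(k, new)] = _merge_distance(linkage, d_ak, d_bk, size[a], size[b])
        del dist[(a, b)]
        active.add(new)
    return Dendrogram(labels=tuple(labels), merges=merges, linkage=linkage)


def cut_clusters(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Flat clustering into exactly ``k`` clusters by cutting the tree."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    assignments = sch.cut_tree(dendrogram.merges, n_clusters=k).ravel()
    return {label: int(c) for label, c in zip(dendrogram.labels, assignments)}


def rank_references(matrix: SimilarityMatrix, query: str) -> list[tuple[str, float]]:
    """All other drugs ranked by descending similarity to ``query``.

    Ties are broken by lexicographic drug id.
    """
    qi = matrix.index(query)
    scores = [
        (d, float(matrix.values[qi, i]))
        for i, d in enumerate(matrix.drug_ids)
        if d != query
    ]
    return sorted(scores, key=lambda ds: (-ds[1], ds[0]))
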