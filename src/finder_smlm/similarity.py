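"""Similarity of clusterings.

Two clusters (index sets) X and Y are *similar* when their overlap exceeds
the number of non-overlapping points of each of them:

    s(X, Y) = 1  iff  |X ∩ Y| > max(|X \\ (X ∩ Y)|, |Y \\ (X ∩ Y)|)

(strict inequality).  The similarity of two clusterings is the number of
similar cluster pairs between them, S(C1, C2) = Σ_{i,j} s(X_i, Y_j); noise
sets are not clusters and never enter the sum.  The assembly score of a
clustering within an assembly A = {C1..Cm} is S̄(Ci, A) = Σ_{j≠i} S(Ci, Cj).

Because similarity demands that the overlap outweigh each side's leftover,
a cluster can be similar to at most one cluster of the other clustering,
so 0 <= S <= min(r, t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Set

import numpy as np

from .density_clustering import NOISE, Clustering

__all__ = [
    "ClusteringAssembly",
    "cluster_pair_similar",
    "clustering_similarity",
    "assembly_similarity",
]


@dataclass(frozen=True)
class ClusteringAssembly:
    """An ordered collection of clusterings of the same point universe."""

    clusterings: tuple[Clustering, ...]

    def __init__(self, clusterings: Sequence[Clustering]) -> None:
        members = tuple(clusterings)
        if not members:
            raise ValueError("assembly must contain at least one clustering")
        n = members[0].n_points
        if any(c.n_points != n for c in members):
            raise ValueError("all clusterings in an assembly must label the same points")
        object.__setattr__(self, "clusterings", members)

    def __len__(self) -> int:
        return len(self.clusterings)

    def __iter__(self):
        return iter(self.clusterings)


def cluster_pair_similar(x: Set[int] | np.ndarray, y: Set[int] | np.ndarray) -> int:
    """1 if index sets X and Y are similar, else 0."""
    xs, ys = set(map(int, x)), set(map(int, y))
    if not xs or not ys:
        raise ValueError("clusters must be non-empty")
    overlap = len(xs & ys)
    return int(overlap > max(len(xs) - overlap, len(ys) - overlap))


def _pair_counts(c1: Clustering, c2: Clustering):
    """Overlap counts |X_i ∩ Y_j| and cluster sizes, via label co-occurrence."""
    l1, l2 = c1.labels, c2.labels
    both = (l1 != NOISE) & (l2 != NOISE)
    size1 = np.bincount(l1[l1 != NOISE], minlength=c1.n_clusters)
    size2 = np.bincount(l2[l2 != NOISE], minlength=c2.n_clusters)
    if not both.any():
        return np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=np.int64), size1, size2
    keys = l1[both] * np.int64(c2.n_clusters) + l2[both]
    uniq, counts = np.unique(keys, return_counts=True)
    pairs = np.stack([uniq // c2.n_clusters, uniq % c2.n_clusters], axis=1)
    return pairs, counts, size1, size2


def clustering_similarity(c1: Clustering, c2: Clustering) -> int:
    """S(C1, C2): the number of similar cluster pairs between two clusterings."""
    if c1.n_points != c2.n_points:
        raise ValueError("clusterings must label the same point universe")
    pairs, counts, size1, size2 = _pair_counts(c1, c2)
    if pairs.shape[0] == 0:
        return 0
    ov = counts
    similar = ov > np.maximum(size1[pairs[:, 0]] - ov, size2[pairs[:, 1]] - ov)
    return int(np.sum(similar))


def assembly_similarity(
    ci: Clustering, assembly: ClusteringAssembly, include_self: bool = False
) -> int:
    """S̄(Ci, A): sum of S(Ci, Cj) over the members of the assembly.

    By default the self term S(Ci, Ci) = r_i is excluded: including it adds
    an offset that grows with the number of clusters and would bias the
    phase-space scan toward over-segmented clusterings.  Set
    ``include_self=True`` for the inclusive sum.
    """
    members = assembly.clusterings
    skip = -1
    if not include_self:
        for idx, cj in enumerate(members):  # exclude exactly one occurrence of ci
            if cj is ci or np.array_equal(cj.labels, ci.labels):
                skip = idx
                break
    return sum(
        clustering_similarity(ci, cj)
        for idx, cj in enumerate(members)
        if idx != skip
    )
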