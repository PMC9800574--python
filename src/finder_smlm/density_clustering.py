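"""Density-based clustering back-ends.

Two cluster definitions share the same (eps, minPts) parameterization:

``dbscan``
    The classic algorithm: clusters grow from core points, border points
    (non-core points within eps of a core point) are attached to the first
    cluster that reaches them, everything else is noise.

``noise_free_dbscan``
    A more conservative variant: all non-core points are removed
    *iteratively* — core status is recomputed on the surviving subset after
    every sweep — until only core points remain.  The survivors are then
    partitioned into clusters as connected components of their
    eps-neighborhood graph.  Because removal can demote previously-core
    points, this variant labels strictly more points as noise than classic
    DBSCAN and never keeps border points.

Throughout, a *core point* is a point with at least ``minPts`` OTHER points
within distance ``eps`` (closed neighborhood, the point itself excluded
from the count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .geometry import LocalizationSet

__all__ = ["ClusteringParams", "Clustering", "dbscan", "noise_free_dbscan", "NOISE"]

#: Label used for noise points.
NOISE = -1

Algorithm = Literal["dbscan", "noise_free_dbscan"]


@dataclass(frozen=True)
class ClusteringParams:
    """The (eps, minPts) pair of a density-based clusterer."""

    eps: float
    minpts: int

    def __post_init__(self) -> None:
        if not (self.eps > 0):
            raise ValueError(f"eps must be positive, got {self.eps}")
        if self.minpts < 1:
            raise ValueError(f"minpts must be >= 1, got {self.minpts}")


@dataclass(frozen=True)
class Clustering:
    """A labeling of N points into disjoint clusters plus a noise set.

    ``labels[i]`` is the cluster id of point i (contiguous ids ``0..r-1``)
    or ``NOISE`` (-1).  Cluster identities are arbitrary; every comparison
    in this package works on the underlying index sets.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        if lab.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        ids = np.unique(lab[lab != NOISE])
        if ids.size and (ids[0] != 0 or ids[-1] != ids.size - 1):
            raise ValueError("cluster ids must be contiguous starting at 0")
        if np.any(lab < NOISE):
            raise ValueError("labels below -1 are not allowed")
        object.__setattr__(self, "labels", lab)

    @property
    def n_points(self) -> int:
        return self.labels.size

    @property
    def n_clusters(self) -> int:
        lab = self.labels
        return int(lab.max()) + 1 if np.any(lab != NOISE) else 0

    @property
    def clusters(self) -> list[np.ndarray]:
        """Index sets X_1..X_r, ordered by cluster id."""
        order = np.argsort(self.labels, kind="stable")
        lab_sorted = self.labels[order]
        start = np.searchsorted(lab_sorted, 0)
        groups = np.split(order[start:], np.searchsorted(lab_sorted[start:], np.arange(1, self.n_clusters)) )
        return groups if self.n_clusters else []

    @property
    def noise_set(self) -> np.ndarray:
        return np.flatnonzero(self.labels == NOISE)

    @property
    def noise_fraction(self) -> float:
        return float(np.mean(self.labels == NOISE)) if self.n_points else 0.0


def _neighbor_graph(points: np.ndarray, eps: float) -> sparse.csr_matrix:
    """Symmetric 0/1 adjacency of the closed eps-neighborhood, no self-loops."""
    n = points.shape[0]
    tree = cKDTree(points)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    if pairs.size == 0:
        return sparse.csr_matrix((n, n), dtype=np.int64)
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    data = np.ones(i.size, dtype=np.int64)
    return sparse.csr_matrix((data, (i, j)), shape=(n, n))


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Map non-noise labels to contiguous ids 0..r-1 in order of first appearance."""
    out = np.full(labels.size, NOISE, dtype=np.int64)
    mapping: dict[int, int] = {}
    for idx in np.flatnonzero(labels != NOISE):
        lab = int(labels[idx])
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[idx] = mapping[lab]
    return out


def dbscan_labels_from_graph(adj: sparse.csr_matrix, minpts: int) -> np.ndarray:
    """Classic DBSCAN on a precomputed eps-neighborhood adjacency.

    Deterministic: seed core points are visited in index order and cluster
    expansion proceeds through a FIFO queue of sorted neighbor lists, so a
    border point reachable from several clusters joins the one whose core
    point reaches it first in that order.
    """
    n = adj.shape[0]
    degree = np.asarray(adj.sum(axis=1)).ravel()
    core = degree >= minpts
    labels = np.full(n, NOISE, dtype=np.int64)
    indptr, indices = adj.indptr, adj.indices

    cluster_id = 0
    for seed in range(n):
        if not core[seed] or labels[seed] != NOISE:
            continue
        labels[seed] = cluster_id
        queue = [seed]
        while queue:
            p = queue.pop(0)
            if not core[p]:
                continue  # border points do not expand the cluster
            for q in indices[indptr[p]:indptr[p + 1]]:
                if labels[q] == NOISE:
                    labels[q] = cluster_id
                    if core[q]:
                        queue.append(q)
        cluster_id += 1
    return labels


def noise_free_labels_from_graph(adj: sparse.csr_matrix, minpts: int) -> np.ndarray:
    """Noise-free cluster definition on a precomputed adjacency.

    Iterates: recompute each surviving point's number of surviving
    neighbors; drop every point below ``minpts``; stop at the fixed point
    where all survivors are core.  Survivors are partitioned into connected
    components of the adjacency restricted to them.
    """
    n = adj.shape[0]
    alive = np.ones(n, dtype=bool)
    while True:
        degree = adj @ alive.astype(np.int64)
        drop = alive & (degree < minpts)
        if not drop.any():
            break
        alive[drop] = False

    labels = np.full(n, NOISE, dtype=np.int64)
    alive_idx = np.flatnonzero(alive)
    if alive_idx.size:
        sub = adj[alive_idx][:, alive_idx]
        _, comp = connected_components(sub, directed=False)
        labels[alive_idx] = comp
    return _relabel_contiguous(labels)


def dbscan(locs: LocalizationSet, params: ClusteringParams) -> Clustering:
    """Classic DBSCAN clustering of a localization set."""
    if locs.n < 1:
        raise ValueError("need at least one point")
    adj = _neighbor_graph(locs.points, params.eps)
    return Clustering(dbscan_labels_from_graph(adj, params.minpts))


def noise_free_dbscan(locs: LocalizationSet, params: ClusteringParams) -> Clustering:
    """Noise-free DBSCAN: iterative non-core removal, then partition.

    The returned clustering satisfies the fixed-point property that every
    non-noise point has at least ``minpts`` non-noise points within eps.
    """
    if locs.n < 1:
        raise ValueError("need at least one point")
    adj = _neighbor_graph(locs.points, params.eps)
    return Clustering(noise_free_labels_from_graph(adj, params.minpts))
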