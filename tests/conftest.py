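"""Shared fixtures and independent brute-force oracles.

Every oracle here is deliberately written without k-d trees, sparse graphs
or vectorized shortcuts shared with the implementation: full pairwise
distance matrices, explicit removal loops and exhaustive double loops, so
the two routes to each answer stay independent.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from finder_smlm import Clustering, NOISE


# ---------------------------------------------------------------- oracles


def canonical_clusters(labels) -> frozenset:
    """Order-free representation: the set of cluster index sets."""
    labs = np.asarray(labels)
    return frozenset(
        frozenset(np.flatnonzero(labs == c).tolist()) for c in np.unique(labs[labs >= 0])
    )


def brute_noise_free(points: np.ndarray, eps: float, minpts: int) -> np.ndarray:
    """Explicit removal loop + hand-rolled component search, O(N^2)."""
    n = len(points)
    dist = cdist(points, points)
    within = dist <= eps
    alive = np.ones(n, dtype=bool)
    while True:
        drop = [
            i for i in range(n)
            if alive[i] and int(np.sum(within[i] & alive)) - 1 < minpts
        ]
        if not drop:
            break
        for i in drop:
            alive[i] = False
    labels = np.full(n, NOISE, dtype=np.int64)
    cid = 0
    for i in range(n):
        if alive[i] and labels[i] == NOISE:
            stack = [i]
            labels[i] = cid
            while stack:
                p = stack.pop()
                for q in range(n):
                    if alive[q] and labels[q] == NOISE and within[p, q]:
                        labels[q] = cid
                        stack.append(q)
            cid += 1
    return labels


def brute_clustering_similarity(c1: Clustering, c2: Clustering) -> int:
    """Exhaustive double loop over all cluster pairs with Python sets."""
    total = 0
    for x in c1.clusters:
        xs = set(x.tolist())
        for y in c2.clusters:
            ys = set(y.tolist())
            ov = len(xs & ys)
            if ov > max(len(xs) - ov, len(ys) - ov):
                total += 1
    return total


def brute_match(truth: Clustering, proposed: Clustering, threshold: float):
    """Exhaustive matcher: enumerate every (X, Y) relation with Python sets.

    Returns (tp, fp, fn, detected_by).
    """
    truths = [set(x.tolist()) for x in truth.clusters]
    props = [set(y.tolist()) for y in proposed.clusters]
    detects = [
        [len(x & y) > threshold * len(x) for y in props] for x in truths
    ]
    # a proposed cluster detecting two truth clusters is disqualified
    for j in range(len(props)):
        if sum(detects[i][j] for i in range(len(truths))) > 1:
            for i in range(len(truths)):
                detects[i][j] = False
    detected_by: list[int | None] = [None] * len(truths)
    credited: set[int] = set()
    for i, x in enumerate(truths):
        best, best_key = None, None
        for j, y in enumerate(props):
            if detects[i][j] and j not in credited:
                key = (len(x & y), -j)  # largest overlap, then smaller id
                if best_key is None or key > best_key:
                    best, best_key = j, key
        if best is not None:
            detected_by[i] = best
            credited.add(best)
    tp = len(credited)
    return tp, len(props) - tp, len(truths) - tp, detected_by


def random_partition(
    n: int, rng: np.random.Generator, max_clusters: int = 6, p_noise: float = 0.25
) -> Clustering:
    """A random labeling of n points into <= max_clusters clusters plus noise."""
    k = int(rng.integers(0, max_clusters + 1))
    labels = np.full(n, NOISE, dtype=np.int64)
    if k:
        labels = rng.integers(0, k, size=n).astype(np.int64)
        labels[rng.random(n) < p_noise] = NOISE
    # enforce contiguous ids over the clusters that survived
    present = np.unique(labels[labels != NOISE])
    remap = {int(c): i for i, c in enumerate(present)}
    labels = np.array([remap.get(int(l), NOISE) for l in labels], dtype=np.int64)
    return Clustering(labels)


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def blob_field(rng):
    """Three dense 12-point blobs (diameter < 1) far apart, plus coordinates."""
    centers = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
    pts = np.concatenate(
        [c + rng.uniform(-0.2, 0.2, size=(12, 2)) for c in centers], axis=0
    )
    return pts
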