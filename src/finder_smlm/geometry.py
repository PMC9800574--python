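"""Neighbor-distance statistics and candidate radius grids.

The radial parameter of a density-based clusterer is only meaningful on the
scale of typical inter-point distances.  This module computes the k-th
nearest-neighbor distance distribution of a localization set and turns it
into an ordered grid of candidate ``eps`` values spanning the 10th to the
90th percentile of that distribution, spaced linearly or geometrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LocalizationSet",
    "EpsilonGrid",
    "kth_neighbor_distances",
    "build_epsilon_grid",
]

Spacing = Literal["linear", "logarithmic"]

#: Percentile bounds of the k-th neighbor distance distribution that the
#: epsilon search interval spans.
PERCENTILE_LO = 10.0
PERCENTILE_HI = 90.0


@dataclass(frozen=True)
class LocalizationSet:
    """An ordered set of 2D localizations with coordinates in nanometers.

    Point order is part of the contract: index ``i`` refers to the same
    localization in every operation of this package, so cluster labels can
    always be written back against the input rows.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must have shape (N, 2), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("all coordinates must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class EpsilonGrid:
    """Ordered candidate values for the radial clustering parameter (nm).

    ``lo`` and ``hi`` are the exact 10th/90th percentiles (linear
    interpolation between order statistics) of the neighbor-distance sample
    the grid was built from; ``values`` spans ``[lo, hi]`` inclusively.
    """

    values: np.ndarray
    k: int | None = None
    lo: float = field(default=np.nan)
    hi: float = field(default=np.nan)
    spacing: Spacing = "logarithmic"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("grid must hold at least one value")
        if np.any(vals <= 0):
            raise ValueError("all grid values must be positive")
        if vals.size > 1 and np.any(np.diff(vals) <= 0):
            raise ValueError("grid values must be strictly increasing")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.n


def kth_neighbor_distances(locs: LocalizationSet, k: int) -> np.ndarray:
    """Euclidean distance from each point to its k-th nearest other point.

    The point itself is excluded from the ranking, so ``k=1`` gives the
    classic nearest-neighbor distance.  Duplicate coordinates are allowed
    and produce zero distances.

    Parameters
    ----------
    locs
        The localization set (N points).
    k
        Neighbor rank, ``1 <= k < N``.

    Returns
    -------
    ndarray of shape (N,) in the input point order.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if locs.n <= k:
        raise ValueError(
            f"need more than k={k} points to rank the k-th neighbor, have N={locs.n}"
        )
    tree = cKDTree(locs.points)
    # query returns the point itself at rank 0 (distance 0, or among ties)
    dists, _ = tree.query(locs.points, k=k + 1)
    return dists[:, k]


def build_epsilon_grid(
    distances: Iterable[float] | np.ndarray,
    n: int = 15,
    spacing: Spacing = "logarithmic",
    k: int | None = None,
) -> EpsilonGrid:
    """Build the candidate eps grid from a neighbor-distance sample.

    The grid spans the 10th to 90th percentile of ``distances`` with ``n``
    points, spaced linearly or geometrically (default: 15 points,
    logarithmic).  Degenerate samples where the two percentiles coincide
    collapse to a single-value grid with a warning.

    Zero distances (duplicate localizations) are dropped before computing
    percentiles for a logarithmic grid, with a warning; negative distances
    are always an error.
    """
    d = np.asarray(list(distances) if not isinstance(distances, np.ndarray) else distances,
                   dtype=float).ravel()
    if d.size == 0:
        raise ValueError("distance sample is empty")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if n < 2:
        raise ValueError(f"grid size n must be >= 2, got {n}")
    if spacing not in ("linear", "logarithmic"):
        raise ValueError(f"spacing must be 'linear' or 'logarithmic', got {spacing!r}")

    if spacing == "logarithmic" and np.any(d == 0):
        n_zero = int(np.sum(d == 0))
        d = d[d > 0]
        if d.size == 0:
            raise ValueError("all distances are zero; cannot build a logarithmic grid")
        warnings.warn(
            f"dropped {n_zero} zero distance(s) (duplicate localizations) "
            "before percentile computation for the logarithmic grid",
            UserWarning,
            stacklevel=2,
        )

    lo, hi = np.percentile(d, [PERCENTILE_LO, PERCENTILE_HI])
    if lo <= 0 and spacing == "linear":
        # a linear grid can still not contain non-positive radii
        raise ValueError("lower percentile of the distance sample is not positive")

    if lo == hi:
        warnings.warn(
            "10th and 90th percentile coincide; eps grid collapses to a single value",
            UserWarning,
            stacklevel=2,
        )
        values = np.array([lo])
    elif spacing == "linear":
        values = np.linspace(lo, hi, n)
    else:
        values = np.geomspace(lo, hi, n)
    return EpsilonGrid(values=values, k=k, lo=float(lo), hi=float(hi), spacing=spacing)
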