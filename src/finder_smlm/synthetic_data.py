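"""Ground-truth-labeled surrogate localization datasets.

The benchmark geometries mirror how SMLM cluster-analysis methods are
stress-tested: compact unit clusters of localizations re-arranged on a
regular grid (probing cluster overlap as the spacing shrinks) or scattered
along a sinusoidal path (probing unstructured layouts), superimposed with
uniform background noise expressed as a fraction of the clustered
localizations.

Unit clusters are isotropic 2D Gaussian blobs with Poisson-distributed
localization counts (minimum 3).  Two presets emulate the statistics of the
experimental unit-cluster libraries such benchmarks are built from:
``low_density`` (sparse synaptic-receptor-like clusters, mean 17
localizations) and ``origami`` (dense DNA-origami binding-site clusters,
mean 113 localizations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import pdist

from .density_clustering import NOISE, Clustering
from .geometry import LocalizationSet

__all__ = [
    "UnitClusterModel",
    "SyntheticDataset",
    "make_grid_dataset",
    "make_sinusoid_dataset",
    "PRESETS",
]

MIN_LOCS_PER_CLUSTER = 3


@dataclass(frozen=True)
class UnitClusterModel:
    """Statistical model of a single cluster of localizations.

    Parameters
    ----------
    mean_localizations
        Mean localization count per cluster (Poisson mean).
    localization_spread
        Standard deviation (nm) of the isotropic Gaussian spatial scatter.
    count_dispersion
        Distribution family for per-cluster counts; only ``"poisson"`` is
        implemented.
    """

    mean_localizations: float = 17.0
    localization_spread: float = 10.0
    count_dispersion: Literal["poisson"] = "poisson"

    def __post_init__(self) -> None:
        if self.mean_localizations < 1:
            raise ValueError("mean_localizations must be >= 1")
        if not (self.localization_spread > 0):
            raise ValueError("localization_spread must be positive")
        if self.count_dispersion != "poisson":
            raise ValueError(f"unknown count_dispersion {self.count_dispersion!r}")

    def sample_cluster(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one cluster centered at the origin."""
        count = max(MIN_LOCS_PER_CLUSTER, int(rng.poisson(self.mean_localizations)))
        return rng.normal(0.0, self.localization_spread, size=(count, 2))


#: Presets matched to the two unit-cluster libraries the benchmarks emulate.
PRESETS: dict[str, UnitClusterModel] = {
    "low_density": UnitClusterModel(mean_localizations=17.0, localization_spread=10.0),
    "origami": UnitClusterModel(mean_localizations=113.0, localization_spread=8.0),
}


@dataclass(frozen=True)
class SyntheticDataset:
    """A surrogate localization set with its ground-truth clustering."""

    locs: LocalizationSet
    truth: Clustering
    layout: Literal["grid", "sinusoid"]
    noise_fraction: float
    seed: int
    max_cluster_diameter: float

    @property
    def n_clusters(self) -> int:
        return self.truth.n_clusters

    def meta(self) -> dict:
        return {
            "layout": self.layout,
            "noise_fraction": self.noise_fraction,
            "seed": self.seed,
            "n_clusters": self.n_clusters,
            "n_points": self.locs.n,
            "max_cluster_diameter_nm": self.max_cluster_diameter,
        }


def _assemble(
    clusters: list[np.ndarray],
    centers: np.ndarray,
    noise_fraction: float,
    layout: Literal["grid", "sinusoid"],
    seed: int,
    rng: np.random.Generator,
    max_diameter: float,
) -> SyntheticDataset:
    """Place sampled clusters at centers and add uniform background noise."""
    placed = [blob + centers[i] for i, blob in enumerate(clusters)]
    clustered = np.vstack(placed)
    labels = np.concatenate(
        [np.full(len(blob), i, dtype=np.int64) for i, blob in enumerate(placed)]
    )

    n_noise = int(round(noise_fraction * clustered.shape[0]))
    if n_noise:
        lo = clustered.min(axis=0) - max_diameter
        hi = clustered.max(axis=0) + max_diameter
        noise = rng.uniform(lo, hi, size=(n_noise, 2))
        points = np.vstack([clustered, noise])
        labels = np.concatenate([labels, np.full(n_noise, NOISE, dtype=np.int64)])
    else:
        points = clustered

    return SyntheticDataset(
        locs=LocalizationSet(points),
        truth=Clustering(labels),
        layout=layout,
        noise_fraction=noise_fraction,
        seed=seed,
        max_cluster_diameter=max_diameter,
    )


def _sample_clusters(model: UnitClusterModel, n: int, rng: np.random.Generator):
    clusters = [model.sample_cluster(rng) for _ in range(n)]
    # realized maximal diameter: largest within-cluster pairwise distance
    max_diameter = max(float(pdist(blob).max()) for blob in clusters)
    return clusters, max_diameter


def make_grid_dataset(
    model: UnitClusterModel,
    rows: int = 5,
    cols: int = 5,
    spacing_factor: float = 1.5,
    noise_fraction: float = 1.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Clusters on a rows x cols grid plus uniform background noise.

    The center-to-center grid spacing is ``spacing_factor`` times the
    realized maximal cluster diameter, so ``spacing_factor = 1`` is the
    high-overlap regime and 1.5 the well-separated one.  Noise points are
    drawn uniformly over the bounding box of the clustered points expanded
    by one maximal diameter on every side; their number is
    ``round(noise_fraction * clustered count)``.  Fully reproducible from
    ``seed``.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if not (spacing_factor > 0):
        raise ValueError("spacing_factor must be positive")
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be non-negative")

    rng = np.random.default_rng(seed)
    clusters, max_diameter = _sample_clusters(model, rows * cols, rng)
    spacing = spacing_factor * max_diameter
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    centers = np.column_stack([jj.ravel() * spacing, ii.ravel() * spacing]).astype(float)
    return _assemble(clusters, centers, noise_fraction, "grid", seed, rng, max_diameter)


def make_sinusoid_dataset(
    model: UnitClusterModel,
    n_clusters: int = 25,
    noise_fraction: float = 1.0,
    seed: int = 0,
    amplitude: float | None = None,
    period: float | None = None,
) -> SyntheticDataset:
    """Clusters at random arc positions along one period of a sine curve.

    Default amplitude and period scale with the realized maximal cluster
    diameter (period = n_clusters x 2 diameters, amplitude = 2.5 diameters).
    Arc positions are sampled uniformly, so occasional pairs of adjacent
    clusters land close enough to overlap — this layout deliberately probes
    the unstructured, variable-separation regime.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be non-negative")

    rng = np.random.default_rng(seed)
    clusters, max_diameter = _sample_clusters(model, n_clusters, rng)
    period_ = period if period is not None else 2.0 * max_diameter * n_clusters
    amplitude_ = amplitude if amplitude is not None else 2.5 * max_diameter
    x = rng.uniform(0.0, period_, size=n_clusters)
    centers = np.column_stack([x, amplitude_ * np.sin(2.0 * np.pi * x / period_)])
    return _assemble(clusters, centers, noise_fraction, "sinusoid", seed, rng, max_diameter)
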