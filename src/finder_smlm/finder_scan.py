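"""The FINDER parameter scan.

The driver selects global (minPts, eps) parameters for a density-based
clusterer without prior knowledge of the data, by rewarding *robustness*:

1. Compute the distribution of k-th neighbor distances (k = 10).
2. Span the eps candidates over its 10th-90th percentile, n = 15 values on
   a logarithmic scale.
3. Let minPts range over the integers 5..20.
4. Cluster the data at every (minPts, eps) combination.
5. Within each iso-minPts row, score every clustering by its summed
   similarity against all other clusterings of that row (the assembly
   score S̄).
6. Per minPts, keep the eps maximizing S̄ — the *line of optima*.
7. Rescale the line scores to [0, 1] by subtracting the minimum and
   dividing by the maximum of the shifted values.
8. Walk the line in increasing minPts and select the first entry whose
   normalized score falls below alpha = 0.5; if none does, fall back to
   the entry with the largest raw score.

Noise acts as the sensitivity floor: clusterings that fluctuate with eps
score low, so the selected parameters sit where the clustering is stable
against parameter perturbation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .config import FinderConfig
from .density_clustering import (
    Clustering,
    ClusteringParams,
    _neighbor_graph,
    dbscan_labels_from_graph,
    noise_free_labels_from_graph,
)
from .geometry import EpsilonGrid, LocalizationSet, build_epsilon_grid, kth_neighbor_distances
from .similarity import ClusteringAssembly, assembly_similarity

__all__ = [
    "ParameterGrid",
    "PhaseSpace",
    "LineOfOptima",
    "LineEntry",
    "FinderResult",
    "compute_phase_space",
    "extract_line_of_optima",
    "select_parameters",
    "run_finder",
]


@dataclass(frozen=True)
class ParameterGrid:
    """The scanned (minPts, eps) combinations plus the scan hyperparameters."""

    minpts_values: tuple[int, ...]
    eps_grid: EpsilonGrid
    k: int = 10

    def __post_init__(self) -> None:
        mp = tuple(int(v) for v in self.minpts_values)
        if not mp or any(v < 1 for v in mp) or any(b <= a for a, b in zip(mp, mp[1:])):
            raise ValueError("minpts_values must be strictly increasing and >= 1")
        object.__setattr__(self, "minpts_values", mp)

    @property
    def n_eps(self) -> int:
        return self.eps_grid.n

    @classmethod
    def from_data(cls, locs: LocalizationSet, config: FinderConfig) -> "ParameterGrid":
        dists = kth_neighbor_distances(locs, config.k)
        grid = build_epsilon_grid(dists, n=config.n_eps, spacing=config.spacing, k=config.k)
        return cls(minpts_values=config.minpts_values, eps_grid=grid, k=config.k)


@dataclass(frozen=True)
class PhaseSpace:
    """Clustering outcome and assembly score for every (minPts, eps) cell.

    Arrays are indexed ``[i_minpts, j_eps]``; ``clusterings[i][j]`` holds
    the full labeling of the cell.
    """

    grid: ParameterGrid
    algorithm: Literal["dbscan", "noise_free_dbscan"]
    clusterings: tuple[tuple[Clustering, ...], ...]
    n_clusters: np.ndarray
    noise_fractions: np.ndarray
    scores: np.ndarray  # S̄, integer-valued

    def cell(self, i: int, j: int) -> Clustering:
        return self.clusterings[i][j]


@dataclass(frozen=True)
class LineEntry:
    minpts: int
    eps: float
    eps_index: int
    raw_score: int
    normalized_score: float


@dataclass(frozen=True)
class LineOfOptima:
    """Per-minPts best eps with raw and normalized assembly scores."""

    entries: tuple[LineEntry, ...]
    degenerate: bool = False  # all raw scores equal; normalization undefined

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class FinderResult:
    selected: ClusteringParams
    clustering: Clustering
    phase_space: PhaseSpace
    line: LineOfOptima
    alpha: float
    fallback_used: bool
    config: FinderConfig

    def to_dict(self) -> dict:
        """JSON-serializable summary (selected params, grid, line, config echo)."""
        from . import __version__

        ps = self.phase_space
        cells = [
            {
                "minpts": int(mp),
                "eps": float(eps),
                "n_clusters": int(ps.n_clusters[i, j]),
                "noise_fraction": float(ps.noise_fractions[i, j]),
                "score": int(ps.scores[i, j]),
            }
            for i, mp in enumerate(ps.grid.minpts_values)
            for j, eps in enumerate(ps.grid.eps_grid.values)
        ]
        return {
            "selected": {"minpts": self.selected.minpts, "eps": self.selected.eps},
            "n_clusters": self.clustering.n_clusters,
            "noise_fraction": self.clustering.noise_fraction,
            "alpha": self.alpha,
            "fallback_used": self.fallback_used,
            "algorithm": ps.algorithm,
            "eps_grid": {
                "values": [float(v) for v in ps.grid.eps_grid.values],
                "lo": ps.grid.eps_grid.lo,
                "hi": ps.grid.eps_grid.hi,
                "spacing": ps.grid.eps_grid.spacing,
                "percentiles": [10.0, 90.0],
                "percentile_interpolation": "linear",
            },
            "line_of_optima": [
                {
                    "minpts": e.minpts,
                    "eps": e.eps,
                    "raw_score": e.raw_score,
                    "normalized_score": e.normalized_score,
                }
                for e in self.line.entries
            ],
            "phase_space": cells,
            "config": self.config.to_dict(),
            "version": __version__,
        }


_LABELERS = {
    "dbscan": dbscan_labels_from_graph,
    "noise_free_dbscan": noise_free_labels_from_graph,
}


def compute_phase_space(
    locs: LocalizationSet,
    grid: ParameterGrid,
    algorithm: Literal["dbscan", "noise_free_dbscan"] = "noise_free_dbscan",
    include_self_similarity: bool = False,
) -> PhaseSpace:
    """Cluster at every grid cell and score each cell within its minPts row.

    The eps-neighborhood graph is built once per eps value and reused for
    every minPts, which is exactly equivalent to clustering each cell from
    scratch.
    """
    labeler = _LABELERS[algorithm]
    n_mp, n_eps = len(grid.minpts_values), grid.n_eps
    clusterings: list[list[Clustering]] = [[None] * n_eps for _ in range(n_mp)]

    for j, eps in enumerate(grid.eps_grid.values):
        adj = _neighbor_graph(locs.points, float(eps))
        for i, minpts in enumerate(grid.minpts_values):
            clusterings[i][j] = Clustering(labeler(adj, minpts))

    if n_eps == 1:
        warnings.warn(
            "eps grid holds a single value; assembly scores are identically 0",
            UserWarning,
            stacklevel=2,
        )

    scores = np.zeros((n_mp, n_eps), dtype=np.int64)
    for i in range(n_mp):
        row = ClusteringAssembly(clusterings[i])
        if n_eps > 1:
            for j in range(n_eps):
                scores[i, j] = assembly_similarity(
                    clusterings[i][j], row, include_self=include_self_similarity
                )

    n_clusters = np.array([[c.n_clusters for c in row] for row in clusterings])
    noise_fractions = np.array([[c.noise_fraction for c in row] for row in clusterings])
    return PhaseSpace(
        grid=grid,
        algorithm=algorithm,
        clusterings=tuple(tuple(row) for row in clusterings),
        n_clusters=n_clusters,
        noise_fractions=noise_fractions,
        scores=scores,
    )


def extract_line_of_optima(ps: PhaseSpace) -> LineOfOptima:
    """Per-minPts argmax over eps, then rescale the optimum scores to [0, 1].

    Ties at the argmax resolve to the smallest eps (a stricter core-point
    condition admits fewer false inclusions).  The rescaling subtracts the
    line minimum and divides by the maximum of the shifted values; if all
    raw scores coincide there is no robustness signal and every normalized
    score is set to 1 with a warning (selection then falls back to the raw
    argmax).
    """
    best_j = np.argmax(ps.scores, axis=1)  # first occurrence = smallest eps
    raw = ps.scores[np.arange(len(best_j)), best_j].astype(float)

    shifted = raw - raw.min()
    degenerate = bool(shifted.max() == 0)
    if degenerate:
        warnings.warn(
            "all line-of-optima scores are equal; normalization undefined, "
            "set to 1 everywhere",
            UserWarning,
            stacklevel=2,
        )
        normalized = np.ones_like(raw)
    else:
        normalized = shifted / shifted.max()

    entries = tuple(
        LineEntry(
            minpts=int(mp),
            eps=float(ps.grid.eps_grid.values[best_j[i]]),
            eps_index=int(best_j[i]),
            raw_score=int(raw[i]),
            normalized_score=float(normalized[i]),
        )
        for i, mp in enumerate(ps.grid.minpts_values)
    )
    return LineOfOptima(entries=entries, degenerate=degenerate)


def select_parameters(
    line: LineOfOptima,
    alpha: float = 0.5,
    direction: Literal["up", "down"] = "up",
) -> tuple[ClusteringParams, bool]:
    """Walk the line of optima and pick the first entry below alpha.

    Entries are traversed in increasing minPts (``direction="up"``, the
    default) or decreasing.  Returns the selected params and a flag that is
    True when no entry fell below alpha and the maximal-raw-score entry was
    used instead.
    """
    if not line.entries:
        raise ValueError("line of optima is empty")
    ordered = line.entries if direction == "up" else tuple(reversed(line.entries))
    for entry in ordered:
        if entry.normalized_score < alpha:
            return ClusteringParams(eps=entry.eps, minpts=entry.minpts), False
    best = max(line.entries, key=lambda e: e.raw_score)
    return ClusteringParams(eps=best.eps, minpts=best.minpts), True


def run_finder(
    locs: LocalizationSet, config: FinderConfig | None = None, **overrides
) -> FinderResult:
    """End-to-end parameter selection; deterministic given input and config."""
    cfg = (config or FinderConfig()).with_overrides(**overrides)
    grid = ParameterGrid.from_data(locs, cfg)
    ps = compute_phase_space(
        locs, grid, algorithm=cfg.algorithm,
        include_self_similarity=cfg.include_self_similarity,
    )
    line = extract_line_of_optima(ps)
    selected, fallback = select_parameters(line, alpha=cfg.alpha, direction=cfg.direction)
    i = grid.minpts_values.index(selected.minpts)
    j = int(np.flatnonzero(np.isclose(grid.eps_grid.values, selected.eps))[0])
    return FinderResult(
        selected=selected,
        clustering=ps.cell(i, j),
        phase_space=ps,
        line=line,
        alpha=cfg.alpha,
        fallback_used=fallback,
        config=cfg,
    )
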