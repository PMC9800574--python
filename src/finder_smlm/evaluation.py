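"""True/false-positive cluster detection against a ground truth.

A ground-truth cluster X is *detected* by a proposed cluster Y when the
overlap covers strictly more than a threshold fraction (default 30%) of X,
|X ∩ Y| > threshold·|X|, and Y does not stand in that relation with any
other ground-truth cluster — one proposed cluster cannot detect two truth
clusters.  Detections are one-to-one: when several proposed clusters each
detect the same truth cluster, the one with the largest overlap is credited
(ties broken toward the smaller cluster id).  Proposed clusters attributed
to a truth cluster are true positives, the rest are false positives;
undetected truth clusters are false negatives.

Noise points of the proposal never participate; truth-noise points inside a
proposed cluster enlarge Y but not the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .density_clustering import NOISE, Clustering

__all__ = ["MatchReport", "match_clusters", "threshold_sweep"]

DEFAULT_OVERLAP_THRESHOLD = 0.3


@dataclass(frozen=True)
class MatchReport:
    """Per-truth-cluster detection status and the TP/FP/FN tallies."""

    detected_by: tuple[int | None, ...]  # proposed cluster id per truth cluster
    tp_count: int
    fp_count: int
    fn_count: int
    overlap_threshold: float

    def to_dict(self) -> dict:
        return {
            "overlap_threshold": self.overlap_threshold,
            "tp": self.tp_count,
            "fp": self.fp_count,
            "fn": self.fn_count,
            "detected_by": [d if d is None else int(d) for d in self.detected_by],
        }


def match_clusters(
    truth: Clustering,
    proposed: Clustering,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> MatchReport:
    """Match proposed clusters to ground-truth clusters by overlap."""
    if truth.n_points != proposed.n_points:
        raise ValueError("truth and proposed clusterings must label the same points")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")

    r, t = truth.n_clusters, proposed.n_clusters
    truth_sizes = np.bincount(truth.labels[truth.labels != NOISE], minlength=r)

    # overlap matrix |X_i ∩ Y_j| over non-noise points of both clusterings
    overlap = np.zeros((r, t), dtype=np.int64)
    both = (truth.labels != NOISE) & (proposed.labels != NOISE)
    if both.any() and r and t:
        np.add.at(overlap, (truth.labels[both], proposed.labels[both]), 1)

    # detection relation: Y_j detects X_i
    detects = overlap > threshold * truth_sizes[:, None] if r and t else np.zeros((r, t), bool)
    # disqualify proposed clusters that detect more than one truth cluster
    multi = detects.sum(axis=0) > 1
    detects[:, multi] = False

    detected_by: list[int | None] = [None] * r
    credited: set[int] = set()
    for i in range(r):
        candidates = np.flatnonzero(detects[i])
        candidates = [j for j in candidates if j not in credited]
        if not candidates:
            continue
        best = max(candidates, key=lambda j: (overlap[i, j], -j))
        detected_by[i] = int(best)
        credited.add(int(best))

    tp = len(credited)
    return MatchReport(
        detected_by=tuple(detected_by),
        tp_count=tp,
        fp_count=t - tp,
        fn_count=r - tp,
        overlap_threshold=float(threshold),
    )


def threshold_sweep(
    truth: Clustering,
    proposed: Clustering,
    thresholds: Sequence[float],
) -> list[MatchReport]:
    """One MatchReport per threshold; TP is non-increasing in the threshold."""
    reports = [match_clusters(truth, proposed, th) for th in thresholds]
    order = np.argsort(np.asarray(thresholds, dtype=float))
    tps = np.array([reports[i].tp_count for i in order])
    if np.any(np.diff(tps) > 0):  # sanity assertion of the metric's monotonicity
        raise AssertionError("TP count increased with a stricter overlap threshold")
    return reports
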