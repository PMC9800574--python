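"""Run configuration for the parameter scan.

Defaults follow the published protocol: the eps search interval is the
10th-90th percentile of the 10th-neighbor distance distribution explored at
15 logarithmically spaced values, minPts spans 5..20, the noise-free
cluster definition is used, and selection stops at the first line-of-optima
entry whose normalized score falls below alpha = 0.5.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Literal

import yaml

__all__ = ["FinderConfig"]


@dataclass(frozen=True)
class FinderConfig:
    k: int = 10
    n_eps: int = 15
    spacing: Literal["linear", "logarithmic"] = "logarithmic"
    minpts_min: int = 5
    minpts_max: int = 20
    alpha: float = 0.5
    algorithm: Literal["dbscan", "noise_free_dbscan"] = "noise_free_dbscan"
    direction: Literal["up", "down"] = "up"
    include_self_similarity: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_eps < 2:
            raise ValueError("n_eps must be >= 2")
        if self.minpts_min < 1 or self.minpts_max < self.minpts_min:
            raise ValueError("need 1 <= minpts_min <= minpts_max")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.algorithm not in ("dbscan", "noise_free_dbscan"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.spacing not in ("linear", "logarithmic"):
            raise ValueError(f"unknown spacing {self.spacing!r}")

    @property
    def minpts_values(self) -> tuple[int, ...]:
        return tuple(range(self.minpts_min, self.minpts_max + 1))

    def to_dict(self) -> dict:
        return asdict(self)

    def with_overrides(self, **kwargs) -> "FinderConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "FinderConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
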