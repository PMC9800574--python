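"""Readers and writers for localization tables and results.

The primary on-disk format is delimited text with named columns: ``x_nm``
and ``y_nm`` (nanometers), or ``x``/``y`` combined with a units flag.
Cluster labels are written back as an extra ``cluster_label`` column with
noise encoded as -1, in the original row order.  An optional reader for
Picasso-style HDF5 localization tables (coordinates in camera pixels) is
provided for convenience.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .density_clustering import NOISE, Clustering
from .geometry import LocalizationSet
from .synthetic_data import SyntheticDataset

__all__ = [
    "LoadedLocalizations",
    "read_localizations",
    "read_picasso_hdf5",
    "write_clustering",
    "read_clustering",
    "write_dataset",
    "read_dataset_truth",
]

logger = logging.getLogger("finder_smlm")

DEFAULT_COLUMNS = ("x_nm", "y_nm")
FALLBACK_COLUMNS = ("x", "y")
LABEL_COLUMN = "cluster_label"
TRUTH_COLUMN = "truth_label"


@dataclass(frozen=True)
class LoadedLocalizations:
    """A localization set together with its source-table bookkeeping."""

    locs: LocalizationSet
    frame: pd.DataFrame  # retained input rows, original column names
    row_indices: np.ndarray  # original 0-based row index of each point
    n_dropped: int


def _resolve_columns(columns, column_map: dict | None, units: str) -> tuple[str, str]:
    if column_map:
        xcol, ycol = column_map.get("x"), column_map.get("y")
        if xcol in columns and ycol in columns:
            return xcol, ycol
        raise ValueError(
            f"mapped columns ({xcol!r}, {ycol!r}) not found; available: {list(columns)}"
        )
    if all(c in columns for c in DEFAULT_COLUMNS):
        return DEFAULT_COLUMNS
    if all(c in columns for c in FALLBACK_COLUMNS):
        if units != "nm":
            raise ValueError(f"columns {FALLBACK_COLUMNS} require units='nm', got {units!r}")
        return FALLBACK_COLUMNS
    raise ValueError(
        f"cannot resolve x/y columns; available headers: {list(columns)} "
        f"(expected {DEFAULT_COLUMNS} or {FALLBACK_COLUMNS})"
    )


def read_localizations(
    path, column_map: dict | None = None, units: str = "nm", sep: str | None = None
) -> LoadedLocalizations:
    """Read a delimited localization table.

    Rows with missing or non-finite coordinates are dropped with a logged
    count; the original row indices of the surviving rows are preserved so
    labels can be written back against the input file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     float_precision="round_trip" if sep is not None else None)
    if df.empty:
        raise ValueError(f"{path} contains no data rows")
    xcol, ycol = _resolve_columns(df.columns, column_map, units)
    xy = df[[xcol, ycol]].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(xy).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d row(s) with missing/non-finite coordinates", n_dropped)
    if not keep.any():
        raise ValueError(f"{path}: no rows with finite coordinates")
    return LoadedLocalizations(
        locs=LocalizationSet(xy[keep]),
        frame=df.loc[keep].reset_index(drop=True),
        row_indices=np.flatnonzero(keep),
        n_dropped=n_dropped,
    )


def read_picasso_hdf5(path, pixel_size_nm: float = 158.0) -> LoadedLocalizations:
    """Read a Picasso ``locs`` HDF5 table; coordinates are camera pixels."""
    import h5py  # optional dependency of this reader only

    with h5py.File(path, "r") as fh:
        locs = fh["locs"][...]
    xy = np.column_stack([locs["x"], locs["y"]]).astype(float) * pixel_size_nm
    keep = np.isfinite(xy).all(axis=1)
    frame = pd.DataFrame({"x_nm": xy[keep, 0], "y_nm": xy[keep, 1]})
    return LoadedLocalizations(
        locs=LocalizationSet(xy[keep]),
        frame=frame,
        row_indices=np.flatnonzero(keep),
        n_dropped=int((~keep).sum()),
    )


def write_clustering(loaded: LoadedLocalizations | LocalizationSet,
                     clustering: Clustering, path) -> None:
    """Write the input columns plus a ``cluster_label`` column (noise = -1)."""
    if isinstance(loaded, LocalizationSet):
        frame = pd.DataFrame({"x_nm": loaded.points[:, 0], "y_nm": loaded.points[:, 1]})
        n = loaded.n
    else:
        frame = loaded.frame.copy()
        n = loaded.locs.n
    if clustering.n_points != n:
        raise ValueError("clustering does not label the given localizations")
    frame[LABEL_COLUMN] = clustering.labels
    frame.to_csv(path, index=False)


def read_clustering(path) -> tuple[LocalizationSet, Clustering]:
    """Read back a table written by :func:`write_clustering`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if LABEL_COLUMN not in df.columns:
        raise ValueError(f"{path} has no {LABEL_COLUMN!r} column")
    xcol, ycol = _resolve_columns(df.columns, None, "nm")
    locs = LocalizationSet(df[[xcol, ycol]].to_numpy(dtype=float))
    return locs, Clustering(df[LABEL_COLUMN].to_numpy(dtype=np.int64))


def write_dataset(dataset: SyntheticDataset, path, sidecar: bool = True) -> None:
    """Write a synthetic dataset as CSV plus a JSON sidecar of its parameters."""
    path = Path(path)
    pd.DataFrame(
        {
            "x_nm": dataset.locs.points[:, 0],
            "y_nm": dataset.locs.points[:, 1],
            TRUTH_COLUMN: dataset.truth.labels,
        }
    ).to_csv(path, index=False)
    if sidecar:
        path.with_suffix(".json").write_text(json.dumps(dataset.meta(), indent=2) + "\n")


def read_dataset_truth(path) -> tuple[LocalizationSet, Clustering]:
    """Read a synthetic dataset CSV, returning points and ground-truth labels."""
    df = pd.read_csv(path, float_precision="round_trip")
    col = TRUTH_COLUMN if TRUTH_COLUMN in df.columns else LABEL_COLUMN
    if col not in df.columns:
        raise ValueError(f"{path} has neither {TRUTH_COLUMN!r} nor {LABEL_COLUMN!r}")
    xcol, ycol = _resolve_columns(df.columns, None, "nm")
    locs = LocalizationSet(df[[xcol, ycol]].to_numpy(dtype=float))
    return locs, Clustering(df[col].to_numpy(dtype=np.int64))
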