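"""Localization tables: data model, CSV/HDF5 I/O, re-segmentation, frame connection.

The working currency of the drift-correction pipeline is a table of
single-molecule localizations with lateral (and optionally axial)
coordinates, a frame index within a dataset, and a dataset index.  A
*dataset* is a contiguous block of frames acquired between brightfield
registration events.  Internally all coordinates are kept in **pixels**
(the nearest-neighbor thresholds are defined in pixels); physical nm
units appear only at I/O boundaries via :class:`UnitSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "UnitSpec",
    "LocalizationTable",
    "FormatError",
    "read_localizations",
    "write_localizations",
    "resegment",
    "reassemble",
    "connect_frames",
]

#: Default lateral pixel size (nm / pixel), matching a 25,600 nm ROI at 256 px.
DEFAULT_PIXEL_SIZE_NM = 100.0

REQUIRED_COLUMNS = ("x", "y", "frame", "dataset")
COORD_COLUMNS_2D = ("x", "y")
COORD_COLUMNS_3D = ("x", "y", "z")


class FormatError(ValueError):
    """Raised for malformed localization files (missing columns, mixed z, ...)."""


@dataclass(frozen=True)
class UnitSpec:
    """How coordinates are expressed on disk.

    Parameters
    ----------
    pixel_size_nm : float
        Physical lateral pixel size in nm/pixel; also used to scale z so
        the Euclidean nearest-neighbor metric is isotropic in pixel units.
    units_on_disk : {"nm", "pixels"}
        Units of the coordinate columns in the file.
    frame_base : int
        0 if frame/dataset indices on disk start at 0, 1 if they start at 1.
    """

    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    units_on_disk: str = "nm"
    frame_base: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.units_on_disk not in ("nm", "pixels"):
            raise ValueError("units_on_disk must be 'nm' or 'pixels'")
        if self.frame_base not in (0, 1):
            raise ValueError("frame_base must be 0 or 1")


@dataclass
class LocalizationTable:
    """A table of localizations in pixel units with 0-based indices.

    Wraps a :class:`pandas.DataFrame` with columns ``x, y[, z], frame,
    dataset`` plus arbitrary pass-through columns (photons, precision, ...).
    Row order is meaningful and preserved by every operation; the ``id``
    column is a stable row identifier assigned at construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing required column: {col!r}")
        if "id" not in df.columns:
            df = df.copy()
            df["id"] = np.arange(len(df), dtype=np.int64)
            self.data = df
        for col in self.coord_columns:
            if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
                raise ValueError(f"non-finite values in column {col!r}")
        frames = df["frame"].to_numpy()
        datasets = df["dataset"].to_numpy()
        if len(df) and (frames.min() < 0 or datasets.min() < 0):
            raise ValueError("frame and dataset indices must be >= 0")
        if len(df):
            present = np.unique(datasets)
            if not np.array_equal(present, np.arange(present[-1] + 1)):
                raise ValueError("dataset indices must form a contiguous range from 0")

    # -- basic accessors ---------------------------------------------------
    @property
    def is_3d(self) -> bool:
        return "z" in self.data.columns

    @property
    def coord_columns(self) -> tuple[str, ...]:
        return COORD_COLUMNS_3D if self.is_3d else COORD_COLUMNS_2D

    @property
    def ndim(self) -> int:
        return 3 if self.is_3d else 2

    @property
    def n_datasets(self) -> int:
        if len(self.data) == 0:
            return 0
        return int(self.data["dataset"].max()) + 1

    def __len__(self) -> int:
        return len(self.data)

    def coords(self) -> np.ndarray:
        """(n, ndim) float array of coordinates in pixels."""
        return self.data.loc[:, list(self.coord_columns)].to_numpy(dtype=float)

    def frames(self) -> np.ndarray:
        return self.data["frame"].to_numpy(dtype=np.int64)

    def datasets(self) -> np.ndarray:
        return self.data["dataset"].to_numpy(dtype=np.int64)

    def dataset_slice(self, d: int) -> "LocalizationTable":
        sub = self.data[self.data["dataset"] == d].copy()
        sub["dataset"] = 0
        return LocalizationTable(sub.reset_index(drop=True))

    def with_coords(self, coords: np.ndarray) -> "LocalizationTable":
        df = self.data.copy()
        for j, col in enumerate(self.coord_columns):
            df[col] = coords[:, j]
        return LocalizationTable(df)

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(self.data.copy())

    @classmethod
    def from_arrays(
        cls,
        x: np.ndarray,
        y: np.ndarray,
        frame: np.ndarray,
        dataset: np.ndarray,
        z: Optional[np.ndarray] = None,
        **extra: np.ndarray,
    ) -> "LocalizationTable":
        cols: dict[str, np.ndarray] = {"x": np.asarray(x, float), "y": np.asarray(y, float)}
        if z is not None:
            cols["z"] = np.asarray(z, float)
        cols["frame"] = np.asarray(frame, np.int64)
        cols["dataset"] = np.asarray(dataset, np.int64)
        cols.update(extra)
        return cls(pd.DataFrame(cols))


# -- file I/O --------------------------------------------------------------

def _from_disk_units(df: pd.DataFrame, spec: UnitSpec) -> pd.DataFrame:
    df = df.copy()
    if spec.units_on_disk == "nm":
        for col in ("x", "y", "z"):
            if col in df.columns:
                df[col] = df[col].astype(float) / spec.pixel_size_nm
    df["frame"] = df["frame"].astype(np.int64) - spec.frame_base
    df["dataset"] = df["dataset"].astype(np.int64) - spec.frame_base
    return df


def _to_disk_units(df: pd.DataFrame, spec: UnitSpec) -> pd.DataFrame:
    df = df.copy()
    if spec.units_on_disk == "nm":
        for col in ("x", "y", "z"):
            if col in df.columns:
                df[col] = df[col].astype(float) * spec.pixel_size_nm
    df["frame"] = df["frame"].astype(np.int64) + spec.frame_base
    df["dataset"] = df["dataset"].astype(np.int64) + spec.frame_base
    return df


def read_localizations(path: str | Path, unit_spec: UnitSpec | None = None) -> LocalizationTable:
    """Read a localization table from CSV or HDF5, converting to pixel units.

    CSV files need a header with at least ``x, y, frame, dataset`` (``z``
    optional); extra columns are passed through untouched.  HDF5 files
    hold one group per dataset with equal-length coordinate arrays.
    """
    spec = unit_spec or UnitSpec()
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5", ".hdf"):
        df = _read_hdf5(path)
    else:
        df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r} in {path.name}")
    if "z" in df.columns and df["z"].isna().any():
        if df["z"].isna().all():
            df = df.drop(columns=["z"])
        else:
            raise FormatError("mixed z presence: some rows have z, others do not")
    return LocalizationTable(_from_disk_units(df, spec))


def _read_hdf5(path: Path) -> pd.DataFrame:
    frames = []
    with h5py.File(path, "r") as f:
        names = sorted(f.keys())
        for name in names:
            grp = f[name]
            cols = {key: grp[key][:] for key in grp.keys()}
            cols["dataset"] = np.full(
                len(next(iter(cols.values()))), int(grp.attrs["dataset"]), dtype=np.int64
            )
            frames.append(pd.DataFrame(cols))
    if not frames:
        return pd.DataFrame({c: [] for c in REQUIRED_COLUMNS})
    return pd.concat(frames, ignore_index=True)


def write_localizations(
    table: LocalizationTable, path: str | Path, unit_spec: UnitSpec | None = None
) -> None:
    """Write a table to CSV or HDF5 in the units requested by ``unit_spec``."""
    spec = unit_spec or UnitSpec()
    path = Path(path)
    df = _to_disk_units(table.data, spec)
    if path.suffix.lower() in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "w") as f:
            f.attrs["pixel_size_nm"] = spec.pixel_size_nm
            f.attrs["units"] = spec.units_on_disk
            for d, sub in df.groupby("dataset", sort=True):
                grp = f.create_group(f"dataset_{int(d):05d}")
                grp.attrs["dataset"] = int(d)
                for col in sub.columns:
                    if col == "dataset":
                        continue
                    grp.create_dataset(col, data=sub[col].to_numpy())
    else:
        df.to_csv(path, index=False)


# -- re-segmentation -------------------------------------------------------

@dataclass
class SegmentationMap:
    """Bookkeeping needed to restore the original dataset/frame scheme."""

    original_dataset: np.ndarray = field(repr=False)
    original_frame: np.ndarray = field(repr=False)
    original_frames_per_dataset: int = 0
    frames_per_dataset: int = 0


def _infer_frames_per_dataset(table: LocalizationTable) -> int:
    """Infer a uniform original dataset length as max(frame)+1.

    Raises if the inference is ambiguous: every dataset except possibly the
    last must actually reach that length (tolerating sparse tables would
    silently corrupt the global frame ordering).
    """
    frames, datasets = table.frames(), table.datasets()
    n = table.n_datasets
    per_max = np.full(n, -1, dtype=np.int64)
    np.maximum.at(per_max, datasets, frames)
    fpd = int(per_max.max()) + 1
    if n > 1 and not np.all(per_max[:-1] == fpd - 1):
        raise ValueError(
            "cannot infer a uniform original dataset length; "
            "pass original_frames_per_dataset explicitly"
        )
    return fpd


def resegment(
    table: LocalizationTable,
    frames_per_dataset: int,
    original_frames_per_dataset: Optional[int] = None,
) -> tuple[LocalizationTable, SegmentationMap]:
    """Re-chunk the global frame sequence into datasets of a requested length.

    The global frame of a row is ``dataset * original_frames_per_dataset +
    frame``; the new indices are its quotient/remainder by
    ``frames_per_dataset``.  Returns the re-indexed table and a mapping for
    :func:`reassemble`.
    """
    if frames_per_dataset < 1:
        raise ValueError("frames_per_dataset must be >= 1")
    orig_fpd = original_frames_per_dataset or _infer_frames_per_dataset(table)
    frames, datasets = table.frames(), table.datasets()
    if np.any(frames >= orig_fpd):
        raise ValueError("frame index exceeds original_frames_per_dataset")
    global_frame = datasets * orig_fpd + frames
    df = table.data.copy()
    df["dataset"] = global_frame // frames_per_dataset
    df["frame"] = global_frame % frames_per_dataset
    mapping = SegmentationMap(
        original_dataset=datasets.copy(),
        original_frame=frames.copy(),
        original_frames_per_dataset=orig_fpd,
        frames_per_dataset=frames_per_dataset,
    )
    return LocalizationTable(df), mapping


def reassemble(table: LocalizationTable, mapping: SegmentationMap) -> LocalizationTable:
    """Restore the original dataset/frame scheme after :func:`resegment`.

    Coordinates are taken from ``table`` (so drift corrections survive);
    indices are restored exactly.  Row order must be unchanged.
    """
    if len(table) != len(mapping.original_dataset):
        raise ValueError("row count changed since resegment; cannot reassemble")
    df = table.data.copy()
    df["dataset"] = mapping.original_dataset
    df["frame"] = mapping.original_frame
    return LocalizationTable(df)


# -- frame connection ------------------------------------------------------

def connect_frames(
    table: LocalizationTable, radius_px: float, max_gap_frames: int = 0
) -> LocalizationTable:
    """Merge repeated localizations of one emitter across consecutive frames.

    Greedy in frame order, independently per dataset: a localization in
    frame f is appended to an open chain whose last member lies within
    ``radius_px`` and no more than ``max_gap_frames + 1`` frames back,
    nearest candidate first.  Each chain collapses to its unweighted
    centroid at the chain's first frame.  This is a pragmatic
    consolidation step — same-emitter blinks separated by long dark times
    are deliberately left unmerged, since repeated returns of an emitter
    are exactly what constrains the drift model downstream.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    if len(table) == 0:
        return table.copy()

    from scipy.spatial import cKDTree

    ndim = table.ndim
    out_rows: list[pd.DataFrame] = []
    for d in range(table.n_datasets):
        sub = table.data[table.data["dataset"] == d]
        coords = sub.loc[:, list(table.coord_columns)].to_numpy(dtype=float)
        frames = sub["frame"].to_numpy(np.int64)
        order = np.argsort(frames, kind="stable")
        coords, frames = coords[order], frames[order]
        sub_sorted = sub.iloc[order]

        # open chains: positions of last member, last frame, accumulators
        chain_last = np.empty((0, ndim))
        chain_lastframe = np.empty(0, np.int64)
        chain_firstframe = np.empty(0, np.int64)
        chain_sum = np.empty((0, ndim))
        chain_count = np.empty(0, np.int64)
        chain_firstrow = np.empty(0, np.int64)  # index into sub_sorted of chain head
        closed: list[tuple[np.ndarray, int, int, int]] = []  # centroid, frame, count, head row

        unique_frames = np.unique(frames)
        for f in unique_frames:
            sel = np.nonzero(frames == f)[0]
            pts = coords[sel]
            # close chains too old to extend
            if len(chain_lastframe):
                stale = (f - chain_lastframe) > (max_gap_frames + 1)
                for ci in np.nonzero(stale)[0]:
                    closed.append(
                        (chain_sum[ci] / chain_count[ci], int(chain_firstframe[ci]),
                         int(chain_count[ci]), int(chain_firstrow[ci]))
                    )
                keep = ~stale
                chain_last, chain_lastframe = chain_last[keep], chain_lastframe[keep]
                chain_firstframe, chain_sum = chain_firstframe[keep], chain_sum[keep]
                chain_count, chain_firstrow = chain_count[keep], chain_firstrow[keep]

            assigned = np.full(len(sel), -1, np.int64)
            if len(chain_last):
                tree = cKDTree(chain_last)
                dist, idx = tree.query(pts, k=1)
                # greedy nearest-candidate-first: sort points by their NN distance
                taken = np.zeros(len(chain_last), bool)
                for pi in np.argsort(dist, kind="stable"):
                    if dist[pi] > radius_px:
                        continue
                    ci = idx[pi]
                    if not taken[ci]:
                        taken[ci] = True
                        assigned[pi] = ci
                    else:
                        # chain already extended this frame; find next free chain
                        k = min(len(chain_last), 8)
                        dd, ii = tree.query(pts[pi], k=k)
                        dd, ii = np.atleast_1d(dd), np.atleast_1d(ii)
                        for d2, c2 in zip(dd, ii):
                            if d2 <= radius_px and not taken[c2]:
                                taken[c2] = True
                                assigned[pi] = c2
                                break
            # extend assigned chains, open new ones for the rest
            for pi, ci in enumerate(assigned):
                if ci >= 0:
                    chain_last[ci] = pts[pi]
                    chain_lastframe[ci] = f
                    chain_sum[ci] = chain_sum[ci] + pts[pi]
                    chain_count[ci] += 1
            new = assigned < 0
            if np.any(new):
                chain_last = np.vstack([chain_last, pts[new]])
                chain_lastframe = np.concatenate([chain_lastframe, np.full(new.sum(), f)])
                chain_firstframe = np.concatenate([chain_firstframe, np.full(new.sum(), f)])
                chain_sum = np.vstack([chain_sum, pts[new]])
                chain_count = np.concatenate([chain_count, np.ones(new.sum(), np.int64)])
                chain_firstrow = np.concatenate([chain_firstrow, sel[new]])

        for ci in range(len(chain_count)):
            closed.append(
                (chain_sum[ci] / chain_count[ci], int(chain_firstframe[ci]),
                 int(chain_count[ci]), int(chain_firstrow[ci]))
            )

        closed.sort(key=lambda t: t[3])
        head_rows = sub_sorted.iloc[[t[3] for t in closed]].copy()
        cent = np.array([t[0] for t in closed]).reshape(len(closed), ndim)
        for j, col in enumerate(table.coord_columns):
            head_rows[col] = cent[:, j]
        head_rows["frame"] = [t[1] for t in closed]
        head_rows["n_merged"] = [t[2] for t in closed]
        out_rows.append(head_rows)

    out = pd.concat(out_rows, ignore_index=True)
    return LocalizationTable(out)
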