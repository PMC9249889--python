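"""In-memory dataset container and HDF5 persistence.

A :class:`Dataset` holds paired single-cell images — an 80x80 2D
transmission image and a 40x40x40 3D side-scatter stack per cell — plus a
metadata table (cell id, subject id, cell type, healthy/diseased label).

Image arrays may be any array-like supporting ``shape`` and integer /
fancy indexing; :meth:`Dataset.select` returns an index-level view so that
subsampling a large cohort never copies pixel data until it is accessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

TRANSMISSION_SHAPE = (80, 80)
SSC_SHAPE = (40, 40, 40)
SCHEMA_VERSION = 1

CELL_TYPES = ("HSC", "LEC")
LABELS = ("healthy", "diseased")


@dataclass(frozen=True)
class ImagePair:
    """One cell's dual-modality image pair with its metadata."""

    transmission: np.ndarray
    ssc: np.ndarray
    subject_id: str
    cell_type: str
    label: str

    def __post_init__(self) -> None:
        t = np.asarray(self.transmission)
        s = np.asarray(self.ssc)
        if t.shape != TRANSMISSION_SHAPE:
            raise ValueError(f"transmission shape {t.shape} != {TRANSMISSION_SHAPE}")
        if s.shape != SSC_SHAPE:
            raise ValueError(f"ssc shape {s.shape} != {SSC_SHAPE}")
        for arr, name in ((t, "transmission"), (s, "ssc")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative intensities")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


class _IndexedView:
    """Lazy fancy-indexed view over a backing image array."""

    def __init__(self, base, indices: np.ndarray):
        self._base = base
        self._indices = np.asarray(indices, dtype=np.int64)

    @property
    def shape(self) -> tuple[int, ...]:
        return (len(self._indices),) + tuple(self._base.shape[1:])

    @property
    def dtype(self):
        return np.asarray(self._base[self._indices[0]]).dtype

    def __len__(self) -> int:
        return len(self._indices)

    def __getitem__(self, item):
        if isinstance(item, (int, np.integer)):
            return np.asarray(self._base[self._indices[item]])
        idx = self._indices[item]
        return np.stack([np.asarray(self._base[i]) for i in idx])

    def __array__(self, dtype=None, copy=None):
        out = self[np.arange(len(self._indices))]
        return out.astype(dtype) if dtype is not None else out


@dataclass
class Dataset:
    """Cohort of image pairs with aligned metadata rows."""

    transmission: object  # array-like (N, 80, 80)
    ssc: object  # array-like (N, 40, 40, 40)
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.meta)
        if self.transmission.shape[0] != n or self.ssc.shape[0] != n:
            raise ValueError("image arrays and metadata row counts differ")
        if tuple(self.transmission.shape[1:]) != TRANSMISSION_SHAPE:
            raise ValueError("transmission array has wrong per-cell shape")
        if tuple(self.ssc.shape[1:]) != SSC_SHAPE:
            raise ValueError("ssc array has wrong per-cell shape")
        missing = {"cell_id", "subject_id", "cell_type", "label"} - set(self.meta)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.meta)

    def pair(self, i: int) -> ImagePair:
        row = self.meta.iloc[i]
        return ImagePair(
            transmission=np.asarray(self.transmission[i]),
            ssc=np.asarray(self.ssc[i]),
            subject_id=str(row.subject_id),
            cell_type=str(row.cell_type),
            label=str(row.label),
        )

    def select(self, indices) -> "Dataset":
        """Index-level subset; image data are gathered lazily on access."""
        indices = np.asarray(indices, dtype=np.int64)
        return Dataset(
            transmission=_IndexedView(self.transmission, indices),
            ssc=_IndexedView(self.ssc, indices),
            meta=self.meta.iloc[indices].reset_index(drop=True),
        )

    def materialize(self) -> "Dataset":
        return Dataset(
            transmission=np.asarray(self.transmission),
            ssc=np.asarray(self.ssc),
            meta=self.meta.copy(),
        )

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    @property
    def subjects(self) -> np.ndarray:
        return self.meta["subject_id"].to_numpy()


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset to HDF5 (images chunked per cell, gzip)."""
    str_dt = h5py.string_dtype("utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        pairs = f.create_group("pairs")
        t = np.asarray(dataset.transmission, dtype=np.float32)
        s = np.asarray(dataset.ssc, dtype=np.float32)
        pairs.create_dataset(
            "transmission", data=t, chunks=(1,) + TRANSMISSION_SHAPE, compression="gzip"
        )
        pairs.create_dataset("ssc", data=s, chunks=(1,) + SSC_SHAPE, compression="gzip")
        meta = f.create_group("meta")
        for col in ("cell_id", "subject_id", "cell_type", "label"):
            meta.create_dataset(col, data=dataset.meta[col].astype(str).to_numpy(), dtype=str_dt)


def read_dataset(path) -> Dataset:
    """Read a dataset written by :func:`write_dataset` (fully into memory)."""
    try:
        f = h5py.File(path, "r")
    except (FileNotFoundError, OSError) as exc:
        raise FileNotFoundError(f"cannot open dataset file: {path}") from exc
    with f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"schema version mismatch in {path}: found {version}, expected {SCHEMA_VERSION}"
            )
        meta = pd.DataFrame(
            {
                col: [v.decode() if isinstance(v, bytes) else str(v) for v in f[f"meta/{col}"][()]]
                for col in ("cell_id", "subject_id", "cell_type", "label")
            }
        )
        return Dataset(
            transmission=f["pairs/transmission"][()],
            ssc=f["pairs/ssc"][()],
            meta=meta,
        )
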