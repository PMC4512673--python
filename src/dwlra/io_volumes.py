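"""Reading and writing DW-MR image series.

A diffusion-weighted series is a collection of 3D volumes, one per
(b-value, diffusion gradient direction, repeat acquisition) triple.  The
:class:`DWSeries` container indexes 2D slices by ``(b, direction, repeat,
slice_index)`` and carries the geometry and acquisition conventions the
rest of the pipeline relies on:

* indices are 0-based everywhere; in-plane arrays are row-major with
  row 0 at the anterior edge by convention,
* shifts are ``(d_row, d_col, d_slice)`` integers, positive meaning
  increasing index,
* slice parity (``slice_index % 2``) identifies the odd/even interleave
  group: with an interleaved protocol the odd-indexed slices are acquired
  in one block and the even-indexed slices in another, so the two parity
  groups sample different respiratory phases.

Volumes are stored as NIfTI-1 files; series metadata travels in a sidecar
CSV with columns ``path,b_value,direction,repeat`` rather than being
parsed from filenames.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "DWSeries",
    "ROIMask",
    "SeriesError",
    "read_series",
    "write_volume",
    "read_roi",
]


class SeriesError(ValueError):
    """A DW series violated its structural contract (missing volumes,
    inconsistent shapes, bad metadata)."""


@dataclass
class DWSeries:
    """Indexed stack of DW-MR volumes keyed by (b, direction, repeat).

    ``volumes[(b, direction, repeat)]`` is a 3D float array of shape
    ``(n_rows, n_cols, n_slices)``.
    """

    volumes: dict
    voxel_size: tuple = (3.0, 3.0, 5.0)
    interleaved: bool = True
    odd_first: bool = True
    b_values: tuple = ()
    directions: tuple = ()
    repeats: tuple = ()

    def __post_init__(self):
        if not self.volumes:
            raise SeriesError("empty series")
        keys = sorted(self.volumes, key=lambda k: (k[0], str(k[1]), k[2]))
        bs = tuple(sorted({k[0] for k in keys}))
        dirs = tuple(sorted({str(k[1]) for k in keys}))
        reps = tuple(sorted({k[2] for k in keys}))
        if not self.b_values:
            self.b_values = bs
        if not self.directions:
            self.directions = dirs
        if not self.repeats:
            self.repeats = reps
        if any(b <= 0 for b in self.b_values):
            raise SeriesError("b-values must be strictly positive")
        if list(self.b_values) != sorted(set(self.b_values)):
            raise SeriesError("b-values must be strictly increasing")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise SeriesError(f"inconsistent volume shapes: {sorted(shapes)}")
        missing = [
            (b, d, r)
            for b in self.b_values
            for d in self.directions
            for r in self.repeats
            if (b, d, r) not in self.volumes
        ]
        if missing:
            raise SeriesError(f"missing (b, direction, repeat) triples: {missing}")

    @property
    def shape(self):
        return next(iter(self.volumes.values())).shape

    @property
    def n_slices(self) -> int:
        return self.shape[2]

    def volume(self, b, direction, repeat) -> np.ndarray:
        try:
            return self.volumes[(b, direction, repeat)]
        except KeyError:
            raise SeriesError(f"no volume for (b={b}, direction={direction}, repeat={repeat})")

    def get_slice(self, b, direction, repeat, slice_index) -> np.ndarray:
        vol = self.volume(b, direction, repeat)
        if not 0 <= slice_index < vol.shape[2]:
            raise SeriesError(
                f"slice_index {slice_index} out of range [0, {vol.shape[2]})"
            )
        return vol[:, :, slice_index]

    def map_volumes(self, fn) -> "DWSeries":
        """Return a new series with ``fn`` applied to every volume."""
        return DWSeries(
            volumes={k: fn(v) for k, v in self.volumes.items()},
            voxel_size=self.voxel_size,
            interleaved=self.interleaved,
            odd_first=self.odd_first,
        )


@dataclass
class ROIMask:
    """Boolean region-of-interest mask for a single slice (2D) or a volume (3D)."""

    mask: np.ndarray
    slice_index: int = 0
    voxel_count: int = field(init=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_count = int(self.mask.sum())
        if self.voxel_count == 0:
            raise ValueError("ROI mask is empty")


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def write_volume(image: np.ndarray, voxel_size, path) -> None:
    """Write a 2D/3D array to a NIfTI-1 file with the given voxel size (mm)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3:
        raise ValueError(f"expected 2D or 3D array, got {image.ndim}D")
    if len(voxel_size) != 3:
        raise ValueError("voxel_size must have 3 entries (dx, dy, dz) in mm")
    img = nib.Nifti1Image(image, _affine(voxel_size))
    img.header.set_zooms(tuple(float(v) for v in voxel_size))
    nib.save(img, os.fspath(path))


def read_volume(path):
    """Read a NIfTI volume; returns (array, voxel_size)."""
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 2:
        data = data[:, :, None]
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def read_series(metadata, base_dir=None, interleaved: bool = True,
                odd_first: bool = True) -> DWSeries:
    """Assemble a :class:`DWSeries` from NIfTI volumes listed in a sidecar table.

    Parameters
    ----------
    metadata : str | pandas.DataFrame
        Path to a CSV with columns ``path, b_value, direction, repeat``
        (one row per volume), or an equivalent DataFrame.
    base_dir : str, optional
        Directory that relative ``path`` entries are resolved against.
        Defaults to the directory of the metadata CSV.
    interleaved, odd_first :
        Slice acquisition convention recorded on the series; with
        ``interleaved`` the odd-index slices form one temporal block and
        the even-index slices the other.
    """
    if isinstance(metadata, (str, os.PathLike)):
        if base_dir is None:
            base_dir = os.path.dirname(os.fspath(metadata))
        metadata = pd.read_csv(metadata)
    required = {"path", "b_value", "direction", "repeat"}
    if not required.issubset(metadata.columns):
        raise SeriesError(
            f"metadata must have columns {sorted(required)}; got {list(metadata.columns)}"
        )
    volumes = {}
    voxel_size = None
    for row in metadata.itertuples(index=False):
        path = row.path
        if base_dir and not os.path.isabs(path):
            path = os.path.join(base_dir, path)
        if not os.path.exists(path):
            raise SeriesError(f"volume file not found: {path}")
        data, zooms = read_volume(path)
        key = (float(row.b_value), str(row.direction), int(row.repeat))
        volumes[key] = data
        voxel_size = zooms
    return DWSeries(
        volumes=volumes,
        voxel_size=voxel_size,
        interleaved=interleaved,
        odd_first=odd_first,
    )


def read_roi(path, slice_index: int = 0) -> ROIMask:
    """Read an ROI mask from a NIfTI file or a 0/255 PNG image."""
    path = os.fspath(path)
    if path.lower().endswith(".png"):
        arr = np.asarray(Image.open(path).convert("L"))
        mask = arr > 127
    else:
        data, _ = read_volume(path)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        mask = data > 0.5
    return ROIMask(mask=mask, slice_index=slice_index)
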