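"""Volumetric I/O and the masked voxel-by-time representation.

All volumes are NIfTI-1 (via nibabel).  A 4-D run is carved into a dense
``V x T`` matrix of gray-matter voxel time courses; per-voxel metric maps are
scattered back onto the 3-D grid.  The voxel linearization is C-order raster
over the grid (last axis fastest), i.e. ``numpy.flatnonzero`` on the boolean
mask, and is identical everywhere in the package so seed/voxel indices are
reproducible across runs and platforms.

Written maps encode out-of-mask voxels as zero; the mask travels alongside.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

__all__ = [
    "TimeSeriesVolume",
    "BrainMask",
    "MaskedTimeSeries",
    "ScalarMap",
    "read_timeseries",
    "read_mask",
    "extract_masked",
    "scatter_map",
    "write_map",
    "read_motion",
    "save_masked",
    "load_masked",
]

#: absolute tolerance (mm) for affine agreement between co-registered images
AFFINE_ATOL_MM = 1e-4


@dataclasses.dataclass
class TimeSeriesVolume:
    """A 4-D functional run: scalar field indexed (i, j, k, t)."""

    data: np.ndarray
    tr_seconds: float
    voxel_size_mm: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("not a time series: expected a 4-D volume, "
                             f"got {self.data.ndim}-D")
        if self.data.shape[3] < 2:
            raise ValueError("time series needs at least 2 frames")
        bad = np.argwhere(~np.isfinite(self.data))
        if bad.size:
            raise ValueError("non-finite value at voxel index "
                             f"{tuple(int(i) for i in bad[0])}")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclasses.dataclass
class BrainMask:
    """A 3-D boolean field naming a tissue compartment."""

    labels: np.ndarray
    role: str = "gray"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(bool)
        if self.labels.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.labels.any():
            raise ValueError("mask is empty")
        if self.role not in {"gray", "white", "csf"}:
            raise ValueError(f"unknown mask role {self.role!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.labels.sum())

    def linear_indices(self) -> np.ndarray:
        """C-order flat indices of the true voxels — the package-wide
        voxel linearization."""
        return np.flatnonzero(self.labels)


@dataclasses.dataclass
class MaskedTimeSeries:
    """V masked voxel time courses of length T, rows in mask raster order."""

    values: np.ndarray          # V x T
    mask: BrainMask
    tr_seconds: float
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be V x T")
        if self.values.shape[0] != self.mask.n_voxels:
            raise ValueError("row count does not match mask voxel count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in masked series")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def coords(self) -> np.ndarray:
        """V x 3 grid coordinates, same order as the rows."""
        return np.argwhere(self.mask.labels)


@dataclasses.dataclass
class ScalarMap:
    """A per-voxel summary statistic defined exactly on a mask."""

    values: np.ndarray          # 3-D; zero outside mask by convention
    mask: BrainMask
    metric_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.mask.labels.shape:
            raise ValueError("map grid does not match mask grid")

    def masked_values(self) -> np.ndarray:
        """The V values on mask voxels, in linearization order."""
        return self.values.ravel()[self.mask.linear_indices()]


def _check_same_grid(shape_a, affine_a, shape_b, affine_b) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(f"grid shape mismatch: {shape_a} vs {shape_b}")
    if affine_a is not None and affine_b is not None:
        if not np.allclose(affine_a, affine_b, atol=AFFINE_ATOL_MM):
            raise ValueError("affine mismatch beyond tolerance "
                             f"({AFFINE_ATOL_MM} mm)")


def read_timeseries(path, tr_seconds: float | None = None) -> TimeSeriesVolume:
    """Read a 4-D NIfTI run.

    Parameters
    ----------
    path : str or Path
        Path to a NIfTI file with >= 2 frames.
    tr_seconds : float, optional
        Repetition time; defaults to the header's time-axis zoom.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"not a time series: {path} is {data.ndim}-D")
    zooms = img.header.get_zooms()
    if tr_seconds is None:
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return TimeSeriesVolume(
        data=data,
        tr_seconds=tr_seconds,
        voxel_size_mm=np.asarray(zooms[:3], dtype=float),
        affine=img.affine,
    )


def read_mask(path, role: str = "gray") -> BrainMask:
    """Read a 3-D binary mask (any nonzero voxel counts as true)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return BrainMask(labels=data != 0, role=role)


def extract_masked(vol: TimeSeriesVolume, mask: BrainMask) -> MaskedTimeSeries:
    """Carve the V x T matrix of mask-voxel time courses out of a 4-D run.

    Rows follow the C-order raster linearization of the mask grid.
    """
    _check_same_grid(vol.data.shape[:3], vol.affine,
                     mask.labels.shape, None)
    flat = vol.data.reshape(-1, vol.data.shape[3])
    values = flat[mask.linear_indices()]
    return MaskedTimeSeries(values=values.copy(), mask=mask,
                            tr_seconds=vol.tr_seconds, affine=vol.affine)


def scatter_map(values: np.ndarray, mask: BrainMask,
                metric_label: str = "") -> ScalarMap:
    """Scatter V per-voxel values back onto the grid (zero off-mask)."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size != mask.n_voxels:
        raise ValueError(
            f"got {values.size} values for {mask.n_voxels} mask voxels")
    grid = np.zeros(mask.labels.size, dtype=np.float64)
    grid[mask.linear_indices()] = values
    return ScalarMap(values=grid.reshape(mask.labels.shape), mask=mask,
                     metric_label=metric_label)


def write_map(smap: ScalarMap, path, affine: np.ndarray | None = None) -> None:
    """Write a ScalarMap as NIfTI (zeros outside the mask)."""
    aff = affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(smap.values.astype(np.float32), aff), str(path))


def read_motion(path) -> np.ndarray:
    """Read a 6-column whitespace-delimited motion-parameter file.

    Columns: 3 translations (mm) then 3 rotations (radians), one row per
    frame.  Returns a T x 6 array.
    """
    arr = np.loadtxt(str(path), ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(
            f"motion file must have 6 columns, got {arr.shape[1]}")
    return arr


# -- exact-round-trip container for masked matrices (HDF5) -------------------

def save_masked(ts: MaskedTimeSeries, path) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("values", data=ts.values)
        f.create_dataset("mask", data=ts.mask.labels.astype(np.uint8))
        f.create_dataset("affine", data=ts.affine)
        f.attrs["tr_seconds"] = ts.tr_seconds
        f.attrs["mask_role"] = ts.mask.role


def load_masked(path) -> MaskedTimeSeries:
    with h5py.File(str(path), "r") as f:
        mask = BrainMask(labels=f["mask"][...].astype(bool),
                         role=str(f.attrs["mask_role"]))
        return MaskedTimeSeries(values=f["values"][...], mask=mask,
                                tr_seconds=float(f.attrs["tr_seconds"]),
                                affine=f["affine"][...])
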