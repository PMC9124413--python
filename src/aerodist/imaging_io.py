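"""Reading and writing 3D nuclear-imaging volumes.

SPECT/CT stacks arrive either as a directory of single-frame DICOM files
(one per anatomical slice) or as plain 3D arrays.  Both paths converge on
:class:`VoxelVolume`, the canonical unit of the homogeneity analysis: a
non-negative 3D intensity grid with a designated slice axis.

Conventions
-----------
* Axis 0 indexes anatomical slices along the main body axis; indices are
  0-based.
* Values are clamped to be non-negative on load.  Iterative SPECT
  reconstructions can produce small negative voxels, and the voxel-ranking
  statistic requires a non-negative measure; the number of clamped voxels
  is logged.
* No resampling or registration is performed: reconstructed voxels are
  analyzed as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset

logger = logging.getLogger(__name__)

__all__ = ["VoxelVolume", "load_dicom_series", "load_raw_volume", "save_raw_volume"]


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D grid of non-negative voxel intensities.

    Parameters
    ----------
    data
        3D array (slices, rows, cols) of non-negative intensities in
        arbitrary calibrated units (counts or activity concentration; the
        homogeneity statistic is invariant to the overall scale).
    slice_axis
        Axis indexing anatomical slices along the main body axis (0 by
        convention).
    voxel_spacing
        Optional physical spacing (mm) per axis, (slice, row, col).
    """

    data: np.ndarray
    slice_axis: int = 0
    voxel_spacing: Optional[tuple] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3D, got {arr.ndim}D")
        if not 0 <= self.slice_axis < 3:
            raise ValueError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")
        if np.any(~np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
        if np.any(arr < 0):
            raise ValueError("volume contains negative values; use load_raw_volume to clamp")
        object.__setattr__(self, "data", arr)

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.slice_axis]

    @property
    def n_rows(self) -> int:
        axes = [a for a in range(3) if a != self.slice_axis]
        return self.data.shape[axes[0]]

    @property
    def n_cols(self) -> int:
        axes = [a for a in range(3) if a != self.slice_axis]
        return self.data.shape[axes[1]]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def total_signal(self) -> float:
        return float(self.data.sum())

    def slices_first(self) -> np.ndarray:
        """Return the data with the slice axis moved to axis 0."""
        return np.moveaxis(self.data, self.slice_axis, 0)


def _clamp_nonnegative(arr: np.ndarray, origin: str) -> np.ndarray:
    negatives = int(np.count_nonzero(arr < 0))
    if negatives:
        logger.warning("%s: clamped %d negative voxel(s) to 0", origin, negatives)
        arr = np.maximum(arr, 0.0)
    return arr


def load_raw_volume(source, slice_axis: int = 0) -> VoxelVolume:
    """Load a 3D array (``.npz`` path from :func:`save_raw_volume`, or an
    in-memory array) into a :class:`VoxelVolume`.

    Negative values are clamped to 0 and the clamp count logged.
    """
    spacing = None
    if isinstance(source, (str, Path)):
        with np.load(source) as npz:
            arr = npz["data"].astype(float)
            slice_axis = int(npz["slice_axis"])
            if "voxel_spacing" in npz:
                spacing = tuple(float(s) for s in npz["voxel_spacing"])
    else:
        arr = np.asarray(source, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D array, got {arr.ndim}D")
    arr = _clamp_nonnegative(arr, "load_raw_volume")
    return VoxelVolume(data=arr, slice_axis=slice_axis, voxel_spacing=spacing)


def save_raw_volume(volume: VoxelVolume, path) -> Path:
    """Write a volume to a lossless portable container (NumPy ``.npz``:
    shape header + float64 values + slice-axis/spacing metadata).

    Inverse of :func:`load_raw_volume`.
    """
    path = Path(path)
    payload = {"data": volume.data, "slice_axis": np.int64(volume.slice_axis)}
    if volume.voxel_spacing is not None:
        payload["voxel_spacing"] = np.asarray(volume.voxel_spacing, dtype=float)
    np.savez(path, **payload)
    # np.savez appends .npz when absent
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def _frame_sort_key(ds: Dataset, filename: str):
    """Anatomical ordering: image position projected on the slice normal
    when present, else instance number, else filename."""
    ipp = getattr(ds, "ImagePositionPatient", None)
    iop = getattr(ds, "ImageOrientationPatient", None)
    if ipp is not None and iop is not None and len(iop) == 6:
        row = np.asarray(iop[:3], dtype=float)
        col = np.asarray(iop[3:], dtype=float)
        normal = np.cross(row, col)
        return (0, float(np.dot(np.asarray(ipp, dtype=float), normal)))
    if ipp is not None:
        return (0, float(ipp[-1]))
    inst = getattr(ds, "InstanceNumber", None)
    if inst is not None:
        return (1, int(inst))
    return (2, filename)


def load_dicom_series(directory, slice_axis_policy: str = "instance") -> VoxelVolume:
    """Read a directory of single-frame DICOM files into a volume.

    Frames are sorted into anatomical order by image-position/instance
    metadata; when neither is present the documented fallback is
    lexicographic filename order (a warning is logged).  Vendor rescale
    slope/intercept are applied, negatives clamped.

    Parameters
    ----------
    directory
        Path holding one series of single-frame files.
    slice_axis_policy
        Kept for interface stability; the stack axis is always axis 0.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ".ima", ""})
    datasets = []
    for p in paths:
        try:
            datasets.append((pydicom.dcmread(p), p.name))
        except Exception:  # non-DICOM stray file
            continue
    if not datasets:
        raise FileNotFoundError(f"no series found in {directory}")

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds, _ in datasets}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent series: frame dimensions {sorted(shapes)}")

    keys = [_frame_sort_key(ds, name) for ds, name in datasets]
    if any(k[0] == 2 for k in keys):
        logger.warning("load_dicom_series: no ordering metadata; falling back to filename order")
    order = sorted(range(len(keys)), key=lambda i: keys[i])

    frames = []
    spacing = None
    for i in order:
        ds, _ = datasets[i]
        frame = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        frames.append(frame * slope + intercept)
        if spacing is None:
            ps = getattr(ds, "PixelSpacing", None)
            st = getattr(ds, "SliceThickness", None)
            if ps is not None and st is not None:
                spacing = (float(st), float(ps[0]), float(ps[1]))

    stack = _clamp_nonnegative(np.stack(frames, axis=0), "load_dicom_series")
    return VoxelVolume(data=stack, slice_axis=0, voxel_spacing=spacing)
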