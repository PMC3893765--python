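"""3D raster I/O: NRRD (read/write interchange) and NIfTI (read).

SimpleITK does the parsing; this module enforces the package's grid
conventions: arrays indexed ``[ix, iy, iz]``, spacing/origin in mm with the
origin at the centre of voxel (0, 0, 0). DICOM is deliberately unsupported.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import SimpleITK as sitk

from .grid import StructureMask, VoxelGrid3D

log = logging.getLogger(__name__)

_READ_EXTS = {".nrrd", ".nhdr", ".nii", ".gz", ".mha", ".mhd"}
_IDENTITY = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


def read_grid(path: str | os.PathLike, format: str | None = None) -> VoxelGrid3D:
    """Read a 3D raster file into a :class:`VoxelGrid3D`.

    Parameters
    ----------
    path : path-like
        NRRD (.nrrd/.nhdr) or NIfTI (.nii/.nii.gz) file.
    format : str, optional
        Ignored hint; the format is detected from the file itself.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    ValueError
        On non-3D data, non-positive spacing, or unsupported format.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _READ_EXTS:
        raise ValueError(f"unsupported format: {ext!r} (supported: NRRD, NIfTI)")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # pragma: no cover - ITK error text varies
        raise ValueError(f"could not read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"non-3D data: {path} has dimension {img.GetDimension()}")
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing {spacing} in {path}")
    direction = img.GetDirection()
    if not np.allclose(direction, _IDENTITY):
        log.warning("read_grid: non-identity direction %s ignored (axis-aligned assumed)", direction)
    # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelGrid3D(values, spacing=spacing, origin=img.GetOrigin())


def write_grid(grid: VoxelGrid3D, path: str | os.PathLike) -> None:
    """Write a grid to NRRD (or any SimpleITK-writable raster format).

    Values are written as float64 so a write/read round-trip preserves
    values, spacing and origin exactly.
    """
    img = sitk.GetImageFromArray(grid.values.transpose(2, 1, 0))
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    sitk.WriteImage(img, os.fspath(path))


def read_mask(path: str | os.PathLike) -> StructureMask:
    """Read a binary target mask; values are binarized at 0.5."""
    grid = read_grid(path)
    return StructureMask(grid.like((grid.values > 0.5).astype(np.float64)))
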