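"""Voxel-grid data model and geometric primitives.

The whole package works on regular 3D rasters. A :class:`VoxelGrid3D` is a
scalar field sampled at voxel centres; the same container carries dose (Gy),
clonogen density (cells/mm^3), distance (mm) and surviving-fraction maps.

Coordinate convention (fixed for I/O interoperability): 0-based indices,
voxel-centre physical coordinates ``x = origin + index * spacing``, i.e. the
origin is the physical position of the centre of voxel (0, 0, 0). Arrays are
indexed ``values[ix, iy, iz]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

_GEOM_TOL = 1e-9  # mm; tolerance for "same geometry" comparisons


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and origin of a regular 3D voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z); all positive.
    spacing : tuple of float
        Voxel size (dx, dy, dz) in mm; all strictly positive.
    origin : tuple of float
        Physical position (mm) of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (identical for every voxel)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-centre coordinates along each axis (mm)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (open) mesh of voxel-centre coordinates."""
        x, y, z = self.axis_coordinates()
        return np.ix_(x, y, z)  # type: ignore[return-value]

    def matches(self, other: "GridGeometry", tol: float = _GEOM_TOL) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )


@dataclass(frozen=True)
class VoxelGrid3D:
    """A 3D scalar field on a regular grid with physical spacing and origin.

    ``values`` is indexed ``[ix, iy, iz]``; its unit depends on the role the
    grid plays (Gy for dose, cells/mm^3 for density, mm for distance,
    dimensionless for survival).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={values.ndim}")
        object.__setattr__(self, "values", values)
        # geometry validation delegated to GridGeometry
        object.__setattr__(
            self, "_geometry", GridGeometry(values.shape, self.spacing, self.origin)
        )
        object.__setattr__(self, "spacing", self._geometry.spacing)
        object.__setattr__(self, "origin", self._geometry.origin)

    _geometry: GridGeometry = field(init=False, repr=False, compare=False)

    @property
    def geometry(self) -> GridGeometry:
        return self._geometry

    @property
    def shape(self) -> tuple[int, int, int]:
        return self._geometry.shape

    @property
    def voxel_volume(self) -> float:
        return self._geometry.voxel_volume

    def like(self, values: np.ndarray) -> "VoxelGrid3D":
        """New grid with the same geometry and the given values."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape != self.values.shape:
            raise ValueError("values shape does not match grid shape")
        return VoxelGrid3D(values, self.spacing, self.origin)

    def same_geometry(self, other: "VoxelGrid3D", tol: float = _GEOM_TOL) -> bool:
        return self._geometry.matches(other._geometry, tol)


@dataclass(frozen=True)
class StructureMask:
    """Binary 3D mask identifying the delineated target on a reference grid."""

    grid: VoxelGrid3D

    def __post_init__(self) -> None:
        vals = self.grid.values
        if not np.all((vals == 0) | (vals == 1)):
            raise ValueError("mask values must be exactly 0 or 1")

    @property
    def array(self) -> np.ndarray:
        """Boolean target indicator array."""
        return self.grid.values.astype(bool)

    @property
    def n_target_voxels(self) -> int:
        return int(self.grid.values.sum())

    @property
    def geometry(self) -> GridGeometry:
        return self.grid.geometry


@dataclass(frozen=True)
class DistanceMap:
    """Per-voxel Euclidean distance (mm) to the nearest target voxel.

    Convention: exactly 0 on every target voxel; for outside voxels, the
    distance from the voxel centre to the nearest target voxel centre
    (not the target surface), respecting anisotropic spacing.
    """

    grid: VoxelGrid3D

    def __post_init__(self) -> None:
        if np.any(self.grid.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def distance_to_target(mask: StructureMask) -> DistanceMap:
    """Euclidean distance map from voxel centres to the nearest target voxel.

    Uses the exact Euclidean distance transform with anisotropic sampling:
    each outside voxel gets the distance from its centre to the nearest
    target voxel centre; target voxels get 0.

    Raises
    ------
    ValueError
        If the mask contains no target voxels.
    """
    if mask.n_target_voxels == 0:
        raise ValueError("empty mask: no target voxels")
    outside = ~mask.array
    dist = ndimage.distance_transform_edt(outside, sampling=mask.grid.spacing)
    return DistanceMap(mask.grid.like(dist))


def masked_volume(mask: StructureMask) -> float:
    """Total volume (mm^3) of the target: voxel count times voxel volume."""
    return mask.n_target_voxels * mask.grid.voxel_volume


def resample_dose_to_structure(
    dose: VoxelGrid3D, structure_grid: VoxelGrid3D | GridGeometry
) -> VoxelGrid3D:
    """Resample a dose grid onto the structure grid's geometry.

    Trilinear interpolation of the dose at every structure voxel centre.
    Structure voxel centres that fall outside the dose grid's physical
    extent (the convex hull of dose voxel centres) receive 0 Gy — SRS dose
    grids are local and the surrounding tissue genuinely receives negligible
    dose; a warning logs the count of such voxels.

    Raises
    ------
    ValueError
        If no structure voxel centre lies inside the dose grid's extent
        (disjoint physical extents).
    """
    geom = structure_grid if isinstance(structure_grid, GridGeometry) else structure_grid.geometry
    if isinstance(structure_grid, VoxelGrid3D) and dose.same_geometry(structure_grid):
        return VoxelGrid3D(dose.values.copy(), dose.spacing, dose.origin)

    # structure voxel centres in dose index space
    axes_idx = [
        (geom.origin[a] + np.arange(geom.shape[a]) * geom.spacing[a] - dose.origin[a])
        / dose.spacing[a]
        for a in range(3)
    ]
    ii, jj, kk = np.meshgrid(*axes_idx, indexing="ij")
    inside = np.ones(geom.shape, dtype=bool)
    for idx, n in zip((ii, jj, kk), dose.shape):
        inside &= (idx >= 0) & (idx <= n - 1)
    if not inside.any():
        raise ValueError("dose and structure grids have disjoint physical extents")

    coords = np.vstack([ii.ravel(), jj.ravel(), kk.ravel()])
    resampled = ndimage.map_coordinates(
        dose.values, coords, order=1, mode="nearest"
    ).reshape(geom.shape)
    n_outside = int((~inside).sum())
    if n_outside:
        resampled[~inside] = 0.0
        log.warning(
            "resample_dose_to_structure: n_voxels_outside_dose_extent=%d set to 0 Gy",
            n_outside,
        )
    return VoxelGrid3D(resampled, geom.spacing, geom.origin)
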