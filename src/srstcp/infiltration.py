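"""Clonogenic-cell density maps under three infiltration scenarios.

Invasive gliomas seed clonogenic cells beyond the delineated target. Three
scenarios are modelled for the density field rho(x):

* ``none`` — cells confined to the target at uniform density rho0.
* ``continuous`` — density decays with distance d (mm) from the target as
  ``rho0 * exp(-d / decay_length)`` up to a cutoff ``d_max`` (default 10 mm,
  the average infiltration depth reported for high-grade gliomas), zero
  beyond.
* ``heterogeneous`` — the same decay coupled with a random (patchy) spatial
  distribution: each outside voxel within the cutoff is independently
  occupied with probability ``exp(-d / decay_length)``; occupied voxels
  carry full density rho0, so the expected density equals the continuous
  scenario voxel by voxel.

rho0 is ``clonogen_number_in_target / target volume`` (default 1e6 cells in
the target); infiltrating cells are additional to that in-target population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DistanceMap, StructureMask, VoxelGrid3D, distance_to_target, masked_volume

SCENARIOS = ("none", "continuous", "heterogeneous")


@dataclass(frozen=True)
class InfiltrationConfig:
    """Scenario selector and parameters of the infiltration model.

    Parameters
    ----------
    scenario : {"none", "continuous", "heterogeneous"}
    d_max_mm : float
        Maximum infiltration distance (mm); density is zero beyond it.
    decay_length_mm : float
        Length scale of the exponential decay, ``f(d) = exp(-d/decay_length)``.
    clonogen_number_in_target : float
        Total clonogenic cells inside the target (sets rho0).
    seed : int, optional
        RNG seed; required by the heterogeneous scenario.
    """

    scenario: str = "none"
    d_max_mm: float = 10.0
    decay_length_mm: float = 1.0
    clonogen_number_in_target: float = 1e6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.d_max_mm <= 0:
            raise ValueError("d_max_mm must be positive")
        if self.decay_length_mm <= 0:
            raise ValueError("decay_length_mm must be positive")
        if self.clonogen_number_in_target <= 0:
            raise ValueError("clonogen_number_in_target must be positive")


@dataclass(frozen=True)
class ClonogenDensityMap:
    """Per-voxel clonogen density (cells/mm^3) with its reference density
    and the target mask it was built from (used for in/out reporting)."""

    grid: VoxelGrid3D
    rho0: float
    mask: StructureMask

    def __post_init__(self) -> None:
        if np.any(self.grid.values < 0):
            raise ValueError("densities must be non-negative")
        if not self.grid.same_geometry(self.mask.grid):
            raise ValueError("density grid and mask grid geometries differ")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    @property
    def total_cells(self) -> float:
        """Total clonogens: sum of density times voxel volume."""
        return float(self.values.sum() * self.grid.voxel_volume)


def _rho0(mask: StructureMask, config: InfiltrationConfig) -> float:
    return config.clonogen_number_in_target / masked_volume(mask)


def _check_dmap(mask: StructureMask, dmap: DistanceMap) -> None:
    if not dmap.grid.same_geometry(mask.grid):
        raise ValueError("distance map and mask are on different grids")


def density_none(mask: StructureMask, config: InfiltrationConfig) -> ClonogenDensityMap:
    """Uniform density rho0 inside the target, zero outside."""
    if mask.n_target_voxels == 0:
        raise ValueError("empty mask")
    rho0 = _rho0(mask, config)
    values = np.where(mask.array, rho0, 0.0)
    return ClonogenDensityMap(mask.grid.like(values), rho0, mask)


def density_continuous(
    mask: StructureMask, dmap: DistanceMap, config: InfiltrationConfig
) -> ClonogenDensityMap:
    """rho0 inside; ``rho0 * exp(-d/decay_length)`` for 0 < d <= d_max; 0 beyond."""
    if mask.n_target_voxels == 0:
        raise ValueError("empty mask")
    _check_dmap(mask, dmap)
    rho0 = _rho0(mask, config)
    d = dmap.values
    decay = rho0 * np.exp(-d / config.decay_length_mm)
    values = np.where(mask.array, rho0, np.where(d <= config.d_max_mm, decay, 0.0))
    return ClonogenDensityMap(mask.grid.like(values), rho0, mask)


def density_heterogeneous(
    mask: StructureMask, dmap: DistanceMap, config: InfiltrationConfig
) -> ClonogenDensityMap:
    """Patchy infiltration: Bernoulli voxel occupancy with the decay as probability.

    Outside the target, each voxel with 0 < d <= d_max is independently
    occupied with probability ``exp(-d/decay_length)``; occupied voxels get
    density rho0, others 0. The expectation over seeds therefore equals
    :func:`density_continuous`. Deterministic for a given seed.
    """
    if mask.n_target_voxels == 0:
        raise ValueError("empty mask")
    _check_dmap(mask, dmap)
    if config.seed is None:
        raise ValueError("heterogeneous scenario requires a seed")
    rho0 = _rho0(mask, config)
    d = dmap.values
    p = np.exp(-d / config.decay_length_mm)
    rng = np.random.default_rng(config.seed)
    occupied = rng.random(d.shape) < p
    values = np.where(
        mask.array,
        rho0,
        np.where((d <= config.d_max_mm) & occupied, rho0, 0.0),
    )
    return ClonogenDensityMap(mask.grid.like(values), rho0, mask)


def build_density(
    mask: StructureMask,
    config: InfiltrationConfig,
    dmap: DistanceMap | None = None,
) -> ClonogenDensityMap:
    """Dispatch on ``config.scenario``; computes the distance map if needed."""
    if config.scenario == "none":
        return density_none(mask, config)
    if dmap is None:
        dmap = distance_to_target(mask)
    if config.scenario == "continuous":
        return density_continuous(mask, dmap, config)
    return density_heterogeneous(mask, dmap, config)
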