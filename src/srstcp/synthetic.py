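"""Synthetic Gamma-Knife-like plans: targets and steep-gradient dose fields.

Real radiosurgery plans are compositions of narrow cross-fired "shots" with
a very steep dose falloff; prescription is conventionally stated at a low
isodose level, e.g. 16 Gy at the 50% isodose (so the maximum dose is 32 Gy).
Here each shot is an anisotropic Gaussian kernel — a stand-in with the same
steep-falloff, 50%-prescription character and closed-form isodose radii:
for an isotropic shot the prescription isodose radius is
``r_p = sigma * sqrt(2 ln(1/isodose_fraction))`` (sigma*sqrt(2 ln 2) at 50%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .grid import GridGeometry, StructureMask, VoxelGrid3D

__all__ = [
    "ShotSpec",
    "PlanSpec",
    "make_ellipsoid_mask",
    "compose_dose",
    "fit_shot_to_target",
]


@dataclass(frozen=True)
class ShotSpec:
    """One Gaussian shot: centre (mm), per-axis sigma (mm), relative weight."""

    centre: tuple[float, float, float]
    sigma: tuple[float, float, float]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma):
            raise ValueError(f"sigma must be strictly positive, got {self.sigma}")
        if self.weight <= 0:
            raise ValueError(f"weight must be strictly positive, got {self.weight}")


@dataclass(frozen=True)
class PlanSpec:
    """A synthetic plan: shots plus prescription and grid geometry.

    After normalization the grid maximum dose equals
    ``prescription_dose / prescription_isodose_fraction`` (32 Gy under the
    16 Gy / 50% defaults).
    """

    shots: tuple[ShotSpec, ...]
    geometry: GridGeometry
    prescription_dose: float = 16.0
    prescription_isodose_fraction: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "shots", tuple(self.shots))
        if len(self.shots) < 1:
            raise ValueError("a plan needs at least one shot")
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be positive")
        if not 0 < self.prescription_isodose_fraction <= 1:
            raise ValueError("prescription_isodose_fraction must be in (0, 1]")

    @property
    def max_dose(self) -> float:
        """Normalized grid-maximum dose in Gy."""
        return self.prescription_dose / self.prescription_isodose_fraction

    def to_dict(self) -> dict:
        return {
            "shots": [
                {"centre": list(s.centre), "sigma": list(s.sigma), "weight": s.weight}
                for s in self.shots
            ],
            "prescription": {
                "dose_gy": self.prescription_dose,
                "isodose_fraction": self.prescription_isodose_fraction,
            },
            "grid": {
                "shape": list(self.geometry.shape),
                "spacing": list(self.geometry.spacing),
                "origin": list(self.geometry.origin),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlanSpec":
        return cls(
            shots=tuple(
                ShotSpec(tuple(s["centre"]), tuple(s["sigma"]), s.get("weight", 1.0))
                for s in d["shots"]
            ),
            geometry=GridGeometry(
                tuple(d["grid"]["shape"]),
                tuple(d["grid"]["spacing"]),
                tuple(d["grid"].get("origin", (0.0, 0.0, 0.0))),
            ),
            prescription_dose=d.get("prescription", {}).get("dose_gy", 16.0),
            prescription_isodose_fraction=d.get("prescription", {}).get(
                "isodose_fraction", 0.5
            ),
        )


def make_ellipsoid_mask(
    centre: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
    geometry: GridGeometry,
) -> StructureMask:
    """Binary mask of voxels whose centres satisfy the ellipsoid inequality.

    A voxel is in the target iff ``sum(((x_i - c_i)/a_i)^2) <= 1`` at its
    centre. Raises ``ValueError`` if no voxel centre lies inside.
    """
    if any(a <= 0 for a in semi_axes):
        raise ValueError(f"semi_axes must be strictly positive, got {semi_axes}")
    xx, yy, zz = geometry.meshgrid()
    q = (
        ((xx - centre[0]) / semi_axes[0]) ** 2
        + ((yy - centre[1]) / semi_axes[1]) ** 2
        + ((zz - centre[2]) / semi_axes[2]) ** 2
    )
    inside = q <= 1.0
    if not inside.any():
        raise ValueError("ellipsoid lies entirely outside the grid (empty mask)")
    return StructureMask(
        VoxelGrid3D(inside.astype(np.float64), geometry.spacing, geometry.origin)
    )


def compose_dose(plan: PlanSpec) -> VoxelGrid3D:
    """Evaluate the plan's dose field on its grid.

    The raw field is the weighted sum of Gaussian shot kernels at voxel
    centres; it is then scaled so the grid maximum equals
    ``prescription_dose / prescription_isodose_fraction`` — the same
    max-normalization a treatment-planning-system export carries.
    """
    geom = plan.geometry
    xx, yy, zz = geom.meshgrid()
    raw = np.zeros(geom.shape, dtype=np.float64)
    for shot in plan.shots:
        cx, cy, cz = shot.centre
        sx, sy, sz = shot.sigma
        raw += shot.weight * np.exp(
            -((xx - cx) ** 2) / (2 * sx**2)
            - ((yy - cy) ** 2) / (2 * sy**2)
            - ((zz - cz) ** 2) / (2 * sz**2)
        )
    peak = raw.max()
    if peak <= 0:
        raise ValueError("all-zero raw dose field; shots do not reach the grid")
    return VoxelGrid3D(raw * (plan.max_dose / peak), geom.spacing, geom.origin)


def fit_shot_to_target(
    mask: StructureMask,
    plan_defaults: PlanSpec | None = None,
    coverage_factor: float = 1.0,
    prescription_dose: float = 16.0,
    prescription_isodose_fraction: float = 0.5,
) -> PlanSpec:
    """Single-shot plan sized to a target's equivalent sphere.

    The shot is centred at the target centroid with isotropic sigma chosen
    so the prescription isodose surface radius equals the target's
    equivalent-sphere radius times ``coverage_factor``: > 1 adds margin,
    < 1 under-covers. Prescription settings come from ``plan_defaults`` when
    given, else from the keyword arguments.
    """
    if mask.n_target_voxels == 0:
        raise ValueError("empty mask")
    if coverage_factor <= 0:
        raise ValueError("coverage_factor must be positive")
    if plan_defaults is not None:
        prescription_dose = plan_defaults.prescription_dose
        prescription_isodose_fraction = plan_defaults.prescription_isodose_fraction

    geom = mask.geometry
    target = mask.array
    idx = np.argwhere(target)
    centroid = tuple(
        geom.origin[a] + idx[:, a].mean() * geom.spacing[a] for a in range(3)
    )
    volume = mask.n_target_voxels * geom.voxel_volume
    r_eq = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    if prescription_isodose_fraction >= 1.0:
        raise ValueError(
            "fit_shot_to_target needs an isodose fraction < 1 "
            "(a Gaussian reaches its maximum only at the centre)"
        )
    r_p = coverage_factor * r_eq
    sigma = r_p / math.sqrt(2.0 * math.log(1.0 / prescription_isodose_fraction))
    shot = ShotSpec(centre=centroid, sigma=(sigma, sigma, sigma), weight=1.0)
    return PlanSpec(
        shots=(shot,),
        geometry=geom,
        prescription_dose=prescription_dose,
        prescription_isodose_fraction=prescription_isodose_fraction,
    )
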