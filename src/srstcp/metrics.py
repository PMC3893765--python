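"""Plan-geometry metrics: the coverage-form conformity index.

CI = (target volume receiving at least the prescription dose) / (target
volume). This is the coverage definition; Paddick-style selectivity terms
are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grid import StructureMask, VoxelGrid3D


@dataclass(frozen=True)
class ConformityResult:
    ci: float
    v_target: float
    v_target_covered: float
    prescription_dose: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci <= 1.0:
            raise ValueError("ci must lie in [0, 1]")


def conformity_index(
    dose: VoxelGrid3D, mask: StructureMask, prescription_dose: float
) -> ConformityResult:
    """Fraction of the target volume covered by the prescription isodose.

    Coverage uses a closed threshold: a voxel at exactly the prescription
    dose counts as covered. Dose must already be on the mask grid.
    """
    if prescription_dose <= 0:
        raise ValueError("prescription_dose must be positive")
    if mask.n_target_voxels == 0:
        raise ValueError("empty mask")
    if not dose.same_geometry(mask.grid):
        raise ValueError("dose and mask are on different grids; resample first")
    vvox = mask.grid.voxel_volume
    inside = mask.array
    n_covered = int((dose.values[inside] >= prescription_dose).sum())
    v_target = mask.n_target_voxels * vvox
    v_covered = n_covered * vvox
    return ConformityResult(
        ci=v_covered / v_target,
        v_target=v_target,
        v_target_covered=v_covered,
        prescription_dose=prescription_dose,
    )
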