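"""Survival maps and NRRD export round trip.

Computes the per-voxel LQ surviving fraction of a plan, writes dose and
survival maps to NRRD, and reads them back. The survival map is the spatial
picture behind the TCP numbers: a very fast increase in surviving fraction
just outside the prescription isodose.
"""

import tempfile
from pathlib import Path

import numpy as np

from srstcp import (
    lq_survival,
    read_grid,
    survival_map,
    synthetic_plan_from_preset,
    write_grid,
)

dose, mask, _, _ = synthetic_plan_from_preset("sphere-margin")
sf = survival_map(dose)

print(f"surviving fraction at 32 Gy (max dose): {lq_survival(32.0):.3e}")
print(f"surviving fraction at 16 Gy (prescription): {lq_survival(16.0):.3e}")
print(f"surviving fraction at the grid edge ({dose.values.min():.1f} Gy): "
      f"{sf.values.max():.3f}")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "survival.nrrd"
    write_grid(sf, path)
    back = read_grid(path)
    exact = np.array_equal(back.values, sf.values)
    print(f"NRRD round trip exact: {exact}, spacing {back.spacing} mm")
# Between the 32 Gy maximum and the grid edge the surviving fraction rises
# by six orders of magnitude — the steep falloff that spares normal tissue
# is precisely what lets infiltrating clonogens survive.
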