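"""End-to-end plan evaluation and fixture generation.

:func:`evaluate_plan` chains the pipeline — resample dose to the structure
grid, compute the distance map, build the per-scenario clonogen density,
evaluate the Poisson TCP and the conformity index — and emits a scenario
report (JSON + CSV, optionally exported maps).

:func:`generate_fixture` writes deterministic synthetic dose/mask/config
triples for named presets, standing in for real treatment-plan exports.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import os
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ScenarioConfig
from .grid import (
    StructureMask,
    VoxelGrid3D,
    distance_to_target,
    masked_volume,
    resample_dose_to_structure,
)
from .infiltration import build_density
from .io import write_grid
from .metrics import ConformityResult, conformity_index
from .radiobiology import TCPResult, compute_tcp, survival_map
from .synthetic import PlanSpec, compose_dose, fit_shot_to_target, make_ellipsoid_mask
from .grid import GridGeometry

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioRow:
    """One report row: TCP and survivor breakdown for one scenario."""

    scenario: str
    tcp: float
    tcp_percent_rounded: float
    expected_survivors: float
    survivors_in_target: float
    survivors_outside_target: float
    replicates: int = 1
    tcp_sd: float | None = None  # across replicates, heterogeneous only


@dataclass(frozen=True)
class EvaluationReport:
    """Per-scenario TCP rows plus conformity index and the resolved config.

    The config echo (including the seed) is sufficient to reproduce every
    number in the report.
    """

    rows: tuple[ScenarioRow, ...]
    ci: ConformityResult
    config: ScenarioConfig
    artifacts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scenarios": [
                {
                    "scenario": r.scenario,
                    "tcp": r.tcp,
                    "tcp_percent_rounded": r.tcp_percent_rounded,
                    "expected_survivors": r.expected_survivors,
                    "survivors_in_target": r.survivors_in_target,
                    "survivors_outside_target": r.survivors_outside_target,
                    "replicates": r.replicates,
                    "tcp_sd": r.tcp_sd,
                }
                for r in self.rows
            ],
            "conformity_index": {
                "ci": self.ci.ci,
                "v_target_mm3": self.ci.v_target,
                "v_target_covered_mm3": self.ci.v_target_covered,
                "prescription_dose_gy": self.ci.prescription_dose,
            },
            "config": self.config.to_dict(),
            "artifacts": self.artifacts,
        }

    def write(self, out_dir: str | os.PathLike) -> dict:
        """Write report.json and report.csv; returns their paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        json_path = out / "report.json"
        with open(json_path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        csv_path = out / "report.csv"
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "scenario",
                    "tcp_percent",
                    "tcp",
                    "expected_survivors",
                    "survivors_in_target",
                    "survivors_outside_target",
                    "replicates",
                    "tcp_sd",
                ]
            )
            for r in self.rows:
                w.writerow(
                    [
                        r.scenario,
                        r.tcp_percent_rounded,
                        repr(r.tcp),
                        repr(r.expected_survivors),
                        repr(r.survivors_in_target),
                        repr(r.survivors_outside_target),
                        r.replicates,
                        "" if r.tcp_sd is None else repr(r.tcp_sd),
                    ]
                )
        return {"json": str(json_path), "csv": str(csv_path)}


def _round_percent(tcp: float, ndigits: int) -> float:
    r = round(100.0 * tcp, ndigits)
    return float(int(r)) if ndigits <= 0 else r


def evaluate_plan(
    dose: VoxelGrid3D,
    mask: StructureMask,
    config: ScenarioConfig,
    out_dir: str | os.PathLike | None = None,
) -> EvaluationReport:
    """Evaluate a dose distribution against a target under the configured scenarios.

    Runs resampling -> distance map -> per-scenario density -> TCP -> CI.
    With ``config.replicates > 1`` the heterogeneous scenario reports the
    mean TCP (and its sd) over replicate seeds ``seed + i``.
    """
    if not config.scenarios:
        raise ValueError("no scenarios requested")
    if not dose.same_geometry(mask.grid):
        dose = resample_dose_to_structure(dose, mask.grid)
    log.info(
        "evaluate_plan: n_voxels=%d n_target_voxels=%d target_volume_mm3=%.2f "
        "min_dose_gy=%.3f max_dose_gy=%.3f",
        dose.values.size,
        mask.n_target_voxels,
        masked_volume(mask),
        dose.values.min(),
        dose.values.max(),
    )

    params = config.radiosensitivity
    needs_distance = any(s != "none" for s in config.scenarios)
    dmap = distance_to_target(mask) if needs_distance else None

    rows: list[ScenarioRow] = []
    for scenario in config.scenarios:
        if scenario == "heterogeneous" and config.replicates > 1:
            results: list[TCPResult] = []
            for i in range(config.replicates):
                dens = build_density(
                    mask, config.infiltration_config(scenario, seed=config.seed + i), dmap
                )
                results.append(compute_tcp(dose, dens, params))
            tcp_mean = statistics.fmean(r.tcp for r in results)
            tcp_sd = statistics.stdev(r.tcp for r in results) if len(results) > 1 else 0.0
            rows.append(
                ScenarioRow(
                    scenario=scenario,
                    tcp=tcp_mean,
                    tcp_percent_rounded=_round_percent(tcp_mean, config.rounding),
                    expected_survivors=statistics.fmean(r.expected_survivors for r in results),
                    survivors_in_target=statistics.fmean(r.survivors_in_target for r in results),
                    survivors_outside_target=statistics.fmean(
                        r.survivors_outside_target for r in results
                    ),
                    replicates=config.replicates,
                    tcp_sd=tcp_sd,
                )
            )
        else:
            dens = build_density(mask, config.infiltration_config(scenario), dmap)
            res = compute_tcp(dose, dens, params)
            rows.append(
                ScenarioRow(
                    scenario=scenario,
                    tcp=res.tcp,
                    tcp_percent_rounded=_round_percent(res.tcp, config.rounding),
                    expected_survivors=res.expected_survivors,
                    survivors_in_target=res.survivors_in_target,
                    survivors_outside_target=res.survivors_outside_target,
                )
            )
        log.info(
            "scenario=%s tcp=%.6g expected_survivors=%.6g total_cells=%.6g",
            scenario,
            rows[-1].tcp,
            rows[-1].expected_survivors,
            dens.total_cells,
        )

    ci = conformity_index(dose, mask, config.prescription_dose)
    artifacts: dict = {}
    report = EvaluationReport(rows=tuple(rows), ci=ci, config=config, artifacts=artifacts)
    if out_dir is not None:
        artifacts.update(report.write(out_dir))
        if config.write_maps:
            out = Path(out_dir)
            sm = survival_map(dose, params)
            write_grid(sm, out / "survival.nrrd")
            write_grid(dose, out / "dose.nrrd")
            if dmap is not None:
                write_grid(dmap.grid, out / "distance.nrrd")
            artifacts["survival_map"] = str(out / "survival.nrrd")
            artifacts["dose_map"] = str(out / "dose.nrrd")
    return report


# --- fixture presets -------------------------------------------------------

# Each preset: target (ellipsoid semi-axes, mm) and shot coverage factor on a
# 1 mm grid spanning the target plus a 12 mm margin.
_PRESETS = {
    "sphere-conformal": {"semi_axes": (10.0, 10.0, 10.0), "coverage": 1.0},
    "sphere-margin": {"semi_axes": (10.0, 10.0, 10.0), "coverage": 1.4},
    "ellipsoid-undercovered": {"semi_axes": (12.0, 10.0, 8.0), "coverage": 0.7},
}

PRESET_NAMES = tuple(_PRESETS)


def synthetic_plan_from_preset(
    preset_name: str, seed: int = 0
) -> tuple[VoxelGrid3D, StructureMask, PlanSpec, ScenarioConfig]:
    """Build the (dose, mask, plan, config) for a named preset in memory."""
    if preset_name not in _PRESETS:
        raise ValueError(f"unknown preset {preset_name!r}; known: {PRESET_NAMES}")
    p = _PRESETS[preset_name]
    margin = 12.0
    half = max(p["semi_axes"]) + margin
    n = int(2 * half) + 1  # 1 mm spacing, odd count so a voxel sits at the centre
    geom = GridGeometry((n, n, n), (1.0, 1.0, 1.0), (-half, -half, -half))
    mask = make_ellipsoid_mask((0.0, 0.0, 0.0), p["semi_axes"], geom)
    plan = fit_shot_to_target(mask, coverage_factor=p["coverage"])
    dose = compose_dose(plan)
    config = ScenarioConfig(seed=seed)
    return dose, mask, plan, config


def generate_fixture(preset_name: str, out_dir: str | os.PathLike, seed: int = 0) -> dict:
    """Write a deterministic NRRD dose + mask pair and a config file.

    Identical bytes for identical (preset, seed). Returns the written paths.
    """
    dose, mask, plan, config = synthetic_plan_from_preset(preset_name, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dose_path = out / "dose.nrrd"
    mask_path = out / "mask.nrrd"
    cfg_path = out / "config.yaml"
    write_grid(dose, dose_path)
    write_grid(mask.grid, mask_path)
    config.to_yaml(cfg_path)
    plan_path = out / "plan.json"
    with open(plan_path, "w") as fh:
        json.dump(plan.to_dict(), fh, indent=2)
    return {
        "dose": str(dose_path),
        "mask": str(mask_path),
        "config": str(cfg_path),
        "plan": str(plan_path),
    }
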