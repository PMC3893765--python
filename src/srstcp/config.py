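"""Scenario configuration: YAML-backed settings for a plan evaluation.

YAML layout::

    prescription: {dose_gy: 16.0, isodose_fraction: 0.5}
    radiobiology: {alpha: 0.24, beta: 0.03, clonogens: 1.0e6}
    infiltration: {scenario: [none, continuous, heterogeneous],
                   d_max_mm: 10.0, decay_length_mm: 1.0, seed: 1}
    output: {maps: false, rounding: 0}

``infiltration.scenario`` may be a single name or a list; the report always
orders rows none, continuous, heterogeneous.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .infiltration import SCENARIOS, InfiltrationConfig
from .radiobiology import RadiosensitivityParams

_SCENARIO_ORDER = {name: i for i, name in enumerate(SCENARIOS)}


@dataclass(frozen=True)
class ScenarioConfig:
    """Fully resolved settings for one evaluation run."""

    prescription_dose: float = 16.0
    prescription_isodose_fraction: float = 0.5
    alpha: float = 0.24
    beta: float = 0.03
    clonogen_number: float = 1e6
    scenarios: tuple[str, ...] = SCENARIOS
    d_max_mm: float = 10.0
    decay_length_mm: float = 1.0
    seed: int = 0
    replicates: int = 1
    write_maps: bool = False
    rounding: int = 0

    def __post_init__(self) -> None:
        scen = tuple(self.scenarios)
        unknown = [s for s in scen if s not in SCENARIOS]
        if unknown:
            raise ValueError(f"unknown scenario name(s): {unknown}")
        if not scen:
            raise ValueError("at least one scenario must be requested")
        # canonical report order: none, continuous, heterogeneous
        object.__setattr__(
            self, "scenarios", tuple(sorted(set(scen), key=_SCENARIO_ORDER.__getitem__))
        )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def radiosensitivity(self) -> RadiosensitivityParams:
        return RadiosensitivityParams(self.alpha, self.beta)

    def infiltration_config(self, scenario: str, seed: int | None = None) -> InfiltrationConfig:
        return InfiltrationConfig(
            scenario=scenario,
            d_max_mm=self.d_max_mm,
            decay_length_mm=self.decay_length_mm,
            clonogen_number_in_target=self.clonogen_number,
            seed=self.seed if seed is None else seed,
        )

    def to_dict(self) -> dict:
        return {
            "prescription": {
                "dose_gy": self.prescription_dose,
                "isodose_fraction": self.prescription_isodose_fraction,
            },
            "radiobiology": {
                "alpha": self.alpha,
                "beta": self.beta,
                "clonogens": self.clonogen_number,
            },
            "infiltration": {
                "scenario": list(self.scenarios),
                "d_max_mm": self.d_max_mm,
                "decay_length_mm": self.decay_length_mm,
                "seed": self.seed,
            },
            "replicates": self.replicates,
            "output": {"maps": self.write_maps, "rounding": self.rounding},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        presc = d.get("prescription", {}) or {}
        rb = d.get("radiobiology", {}) or {}
        inf = d.get("infiltration", {}) or {}
        out = d.get("output", {}) or {}
        scen = inf.get("scenario", list(SCENARIOS))
        if isinstance(scen, str):
            scen = [scen]
        return cls(
            prescription_dose=float(presc.get("dose_gy", 16.0)),
            prescription_isodose_fraction=float(presc.get("isodose_fraction", 0.5)),
            alpha=float(rb.get("alpha", 0.24)),
            beta=float(rb.get("beta", 0.03)),
            clonogen_number=float(rb.get("clonogens", 1e6)),
            scenarios=tuple(scen),
            d_max_mm=float(inf.get("d_max_mm", 10.0)),
            decay_length_mm=float(inf.get("decay_length_mm", 1.0)),
            seed=int(inf.get("seed", 0)),
            replicates=int(d.get("replicates", 1)),
            write_maps=bool(out.get("maps", False)),
            rounding=int(out.get("rounding", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
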