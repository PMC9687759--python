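"""Simulation configuration: dataclasses with YAML round-trip.

Every numeric default is either a value from the source parameter tables
(tissue constants, frequency, default power and ablation time, slot
dimensions) or an external-literature default (coax radii, perfusion,
Arrhenius kinetics, dielectric sigmoids); the YAML written by
:func:`SimulationConfig.to_yaml` carries provenance comments.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bioheat import PerfusionModel
from .damage import ArrheniusParams


@dataclass
class AntennaConfig:
    slot_count: int = 10
    slot_width: float = 0.6e-3  # m
    slot_spacing: float = 0.8e-3  # m
    inner_conductor_radius: float = 0.14e-3
    dielectric_outer_radius: float = 0.47e-3
    outer_conductor_thickness: float = 0.10e-3
    catheter_outer_radius: float = 0.895e-3
    tip_offset: float = 1.0e-3
    insertion_depth: float = 40.0e-3


@dataclass
class TumorConfig:
    kind: str = "ellipsoid"  # ellipsoid | surface_mesh
    semi_axes: tuple[float, float, float] = (8.2e-3, 8.55e-3, 19.05e-3)
    center_z: float | None = None  # default: middle of the slotted span
    surface_path: str | None = None


@dataclass
class MeshConfig:
    domain_radius: float = 35.0e-3
    z_max: float = 25.0e-3
    h_fine: float = 0.35e-3
    h_coarse: float = 3.0e-3
    h_coax: float = 0.11e-3
    growth: float = 0.25


@dataclass
class SimulationConfig:
    """Full description of one ablation simulation."""

    frequency: float = 2.45e9  # Hz
    input_power: float = 13.0  # W
    ablation_time: float = 600.0  # s
    dt: float = 1.0  # s
    backend: str = "pennes"  # pennes | lte | ltne
    vaporization: str = "effective_heat"  # effective_heat | enthalpy | none
    beta_model: str = "step"  # step | smooth
    em_resolve_dT: float = 5.0  # degC drift triggering an EM re-solve
    em_resolve_interval: float = 30.0  # s between forced EM re-solves
    metrics_interval: float = 10.0  # s between coverage snapshots
    rng_seed: int = 0
    antenna: AntennaConfig = field(default_factory=AntennaConfig)
    tumor: TumorConfig = field(default_factory=TumorConfig)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    perfusion: PerfusionModel = field(default_factory=PerfusionModel)
    arrhenius: ArrheniusParams = field(default_factory=ArrheniusParams)

    def __post_init__(self) -> None:
        if self.input_power < 0:
            raise ValueError("input power must be non-negative")
        if self.ablation_time <= 0 or self.dt <= 0:
            raise ValueError("ablation time and dt must be positive")
        if self.backend not in ("pennes", "lte", "ltne"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.vaporization not in ("effective_heat", "enthalpy", "none"):
            raise ValueError(f"unknown vaporization {self.vaporization!r}")
        if self.beta_model not in ("step", "smooth"):
            raise ValueError(f"unknown beta model {self.beta_model!r}")

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["perfusion"]["u"] = list(self.perfusion.u)
        d["tumor"]["semi_axes"] = list(self.tumor.semi_axes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        sub = {
            "antenna": AntennaConfig,
            "tumor": TumorConfig,
            "mesh": MeshConfig,
            "perfusion": PerfusionModel,
            "arrhenius": ArrheniusParams,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sub:
                if key == "perfusion" and "u" in val:
                    val = dict(val)
                    val["u"] = tuple(val["u"])
                if key == "tumor" and "semi_axes" in val:
                    val = dict(val)
                    val["semi_axes"] = tuple(val["semi_axes"])
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(_YAML_HEADER + yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kwargs) -> "SimulationConfig":
        d = self.to_dict()
        for k, v in kwargs.items():
            if isinstance(v, dict) and k in d and isinstance(d[k], dict):
                d[k].update(v)
            else:
                d[k] = v
        return SimulationConfig.from_dict(d)


_YAML_HEADER = """\
# mwablate simulation configuration.
# Provenance of defaults:
#   frequency 2.45 GHz, input_power 13 W, ablation_time 600 s  [source parameter set]
#   slot_width 0.6 mm, slot_spacing 0.8 mm, slot_count 10      [source antenna schematic]
#   tissue/blood density, conductivity, specific heat          [source material table]
#   coax radii (50-ohm PTFE), perfusion omega_b/porosity/h_c_a,
#   Arrhenius A & dE, dielectric sigmoid coefficients          [external literature]
"""
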