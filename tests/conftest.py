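"""Shared fixtures: coarse meshes sized so the suite runs on one CPU."""

from __future__ import annotations

import numpy as np
import pytest

from mwablate import SimulationConfig, build_geometry
from mwablate import geometry as G


@pytest.fixture(scope="session")
def coarse_config() -> SimulationConfig:
    """Scaled-down simulation: coarse mesh, 2.5 s steps, smaller domain."""
    return SimulationConfig().replace(
        mesh={
            "h_fine": 0.9e-3,
            "h_coarse": 4.5e-3,
            "domain_radius": 30e-3,
            "z_max": 20e-3,
        },
        dt=2.5,
        ablation_time=600.0,
    )


@pytest.fixture(scope="session")
def coarse_mesh(coarse_config):
    _, _, mesh = build_geometry(coarse_config)
    return mesh


@pytest.fixture(scope="session")
def antenna():
    return G.build_antenna()


@pytest.fixture()
def insulated_tagger():
    return lambda r, z: "insulated"
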