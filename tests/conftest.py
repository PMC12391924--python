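"""Shared fixtures: small geometries and leadfields, built once per session."""

import numpy as np
import pytest

from meginverse import (
    assemble_leadfield,
    build_sensor_helmet,
    build_source_grid,
)


@pytest.fixture(scope="session")
def helmet32():
    return build_sensor_helmet(32, radius=0.12, cap_fraction=0.6)


@pytest.fixture(scope="session")
def grid20mm():
    """Coarse 2-cm lattice in an 8-cm sphere (~250 dipoles)."""
    return build_source_grid(radius=0.08, spacing=0.02, orientation_seed=0)


@pytest.fixture(scope="session")
def leadfield32(helmet32, grid20mm):
    return assemble_leadfield(helmet32, grid20mm)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
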