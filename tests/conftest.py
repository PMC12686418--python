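"""Shared fixtures: small calibrated engine runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from ioert.beam import Applicator, BeamSource, build_machine, default_stack
from ioert.transport import TransportConfig, run_simulation, water_phantom

SOURCE_9MEV = BeamSource(9.8, 0.9, 1.6, 0.0)
SOURCE_6MEV = BeamSource(7.2, 0.7, 1.6, 0.0)


@pytest.fixture(scope="session")
def reference_geometry():
    """Default machine head with the 10 cm reference applicator."""
    return build_machine(default_stack(), Applicator(diameter=10.0))


@pytest.fixture(scope="session")
def small_phantom():
    """120 mm wide, 60 mm deep water tank at 1 mm voxels."""
    return water_phantom(side_mm=120.0, depth_mm=60.0, spacing_mm=1.0)


@pytest.fixture(scope="session")
def grid_9mev(reference_geometry, small_phantom):
    """Moderate-statistics 9 MeV reference-field run shared by many tests."""
    config = TransportConfig(seed=42, n_histories=200_000)
    return run_simulation(SOURCE_9MEV, reference_geometry, small_phantom, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
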