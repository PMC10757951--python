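import numpy as np
import pytest

from osteovox.config import PhantomSpec, SimConfig
from osteovox.geometry import SimulationLattice, build_phantom


@pytest.fixture
def tiny_spec() -> PhantomSpec:
    """Smallest sensible osteotomy phantom (cortex 3 voxels thick)."""
    return PhantomSpec(
        outer_radius_um=63.0, inner_radius_um=31.5, fragment_length_um=105.0,
        gap_width_um=84.0, margin_xy_um=21.0, margin_z_um=21.0)


@pytest.fixture
def tiny_phantom(tiny_spec) -> SimulationLattice:
    return build_phantom(tiny_spec)


@pytest.fixture
def soft_lattice() -> SimulationLattice:
    """All-soft-tissue lattice for agent behaviour tests."""
    return SimulationLattice.empty((12, 12, 12))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def config() -> SimConfig:
    return SimConfig()
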