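import numpy as np
import pytest

from j45dose.cross_sections import load_cross_sections
from j45dose.fluence import scenario_grid, synthesize_fluence
from j45dose.phantom import build_ds8602_adult
from j45dose.quadrature import (
    build_base_quadrature,
    mirror_asymmetric,
    refine_polar,
)
from j45dose.voxel import voxelize


@pytest.fixture(scope="session")
def base_quadrature():
    return build_base_quadrature()


@pytest.fixture(scope="session")
def symmetric240(base_quadrature):
    return refine_polar(base_quadrature, 5)


@pytest.fixture(scope="session")
def asymmetric480(symmetric240):
    return mirror_asymmetric(symmetric240)


@pytest.fixture(scope="session")
def io_scenario():
    """Hiroshima, 1000 m, in-open: the headline reference condition."""
    return synthesize_fluence(scenario_grid()[0], seed=20)


@pytest.fixture(scope="session")
def adult_phantom():
    return build_ds8602_adult()


@pytest.fixture(scope="session")
def adult_voxels(adult_phantom):
    """Coarse working resolution used by the transport tests."""
    return voxelize(adult_phantom, 1.0)


@pytest.fixture(scope="session")
def adult_voxels_fine(adult_phantom):
    """Fine enough to resolve the smallest organs (eye lens)."""
    return voxelize(adult_phantom, 0.5)


@pytest.fixture(scope="session")
def xs():
    return load_cross_sections()
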