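import numpy as np
import pytest

from stoichspindle import CellGeometry, LayoutSpec, MotorMTParams, place_cfgs


@pytest.fixture(scope="session")
def default_params() -> MotorMTParams:
    return MotorMTParams()


@pytest.fixture(scope="session")
def default_geom() -> CellGeometry:
    return CellGeometry()


@pytest.fixture(scope="session")
def wildtype_layout(default_geom):
    """One canonical 100-CFG 60/40 layout, shared across tests."""
    return place_cfgs(default_geom, LayoutSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
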