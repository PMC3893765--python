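import numpy as np
import pytest

from srstcp import (
    GridGeometry,
    ScenarioConfig,
    compose_dose,
    fit_shot_to_target,
    make_ellipsoid_mask,
)


@pytest.fixture(scope="session")
def sphere_geometry():
    """1 mm grid spanning a 10 mm-radius target plus a 12 mm margin."""
    return GridGeometry((45, 45, 45), (1.0, 1.0, 1.0), (-22.0, -22.0, -22.0))


@pytest.fixture(scope="session")
def sphere_mask(sphere_geometry):
    """Digitized 10 mm-radius spherical target centred at the origin."""
    return make_ellipsoid_mask((0.0, 0.0, 0.0), (10.0, 10.0, 10.0), sphere_geometry)


@pytest.fixture(scope="session")
def covered_plan(sphere_mask):
    """Single-shot plan with margin: prescription isodose at 1.3x the target radius."""
    return fit_shot_to_target(sphere_mask, coverage_factor=1.3)


@pytest.fixture(scope="session")
def covered_dose(covered_plan):
    return compose_dose(covered_plan)


@pytest.fixture
def default_config():
    return ScenarioConfig(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
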