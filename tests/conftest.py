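import numpy as np
import pytest

from echonav import (
    BinauralGainModel,
    EmissionModel,
    Environment,
    Scatterer,
    make_arena,
    make_corridor,
)


@pytest.fixture(scope="session")
def arena():
    return make_arena(1)


@pytest.fixture(scope="session")
def corridor():
    return make_corridor(2)


@pytest.fixture(scope="session")
def emission():
    return EmissionModel()


@pytest.fixture(scope="session")
def ears():
    return BinauralGainModel()


def lone_scatterer_env(x, y, strength=0.05):
    """Open scene with a single point reflector (for end-to-end sonar checks)."""
    return Environment(
        kind="arena",
        walls=[],
        obstacles=[],
        scatterers=[Scatterer((x, y), strength)],
        bounds=(-10.0, -10.0, 10.0, 10.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
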