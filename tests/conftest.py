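import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pottsmc import CellIndexModel, Configuration, Lattice  # noqa: E402


@pytest.fixture
def ring4():
    """4-site periodic ring, nearest-neighbor copy and interface neighborhoods."""
    return Lattice((4,))


@pytest.fixture
def cells2():
    """Two cells plus medium, generic type."""
    return CellIndexModel(2)


@pytest.fixture
def grid3x3():
    return Lattice((3, 3))


@pytest.fixture
def random_config_factory(grid3x3):
    """Random 3x3 configurations over Sigma = {0, 1, 2}, seeded per call."""
    cells = CellIndexModel(2)

    def make(seed):
        rng = np.random.default_rng(seed)
        return Configuration(grid3x3, cells, rng.integers(0, 3, size=9))

    return make
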