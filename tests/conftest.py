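import numpy as np
import pytest

from islandcoal import IslandScenario, ScalingConfig, make_log_grid


@pytest.fixture
def scaling():
    return ScalingConfig()


@pytest.fixture
def single_component():
    """n=10 islands, one migration regime."""
    return IslandScenario(10, 1000.0, (), (1.0,))


@pytest.fixture
def two_component():
    """Connectivity increase (M 1 -> 5) at one coalescent unit in the past."""
    return IslandScenario(10, 1000.0, (1.0,), (1.0, 5.0))


@pytest.fixture
def panmictic():
    return IslandScenario(1, 5000.0, (), (0.0,))


@pytest.fixture
def coal_grid():
    return make_log_grid(0.01, 50.0, 64)
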