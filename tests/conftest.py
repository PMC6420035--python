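import numpy as np
import pytest

from surfcol import SimulationParams, StrategySpec


@pytest.fixture
def params():
    """Default parameter set (the standard study conditions)."""
    return SimulationParams()


@pytest.fixture
def ra_params():
    """Random-attachment variant at the balanced rate (A_RA = D)."""
    return SimulationParams(strategy=StrategySpec.random_attachment(0.01))


@pytest.fixture
def short_params():
    """One diel cycle with a small founder population: fast smoke runs."""
    return SimulationParams(n_days=1, N0=30)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
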