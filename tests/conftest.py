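import numpy as np
import pytest
from hypothesis import settings

from mapsnn import NeuronParams, SimulationConfig

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def params_tau4_r2() -> NeuronParams:
    """The low-resistance panel of the constant-current protocol."""
    return NeuronParams(tau=4.0, R=2.0, v_th=1.0)


@pytest.fixture
def cfg_1s():
    def make(dt: float, I: float = 1.0, v0: float = 0.0) -> SimulationConfig:
        return SimulationConfig(current=I, total_time=1000.0, dt=dt, initial_v=v0)
    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
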