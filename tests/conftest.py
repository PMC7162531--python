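import numpy as np
import pytest
from hypothesis import settings

from pitburst import DEFAULT_PARAMS, simulate
from pitburst.simulate import NoiseFlags, SimulationConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def det_trace():
    """Deterministic default-parameter run (periodic spiking), shared
    across tests to amortise the simulation."""
    cfg = SimulationConfig(duration=6000.0, noise=NoiseFlags.none(),
                           transient_discard=1000.0)
    return simulate(DEFAULT_PARAMS, cfg)


@pytest.fixture(scope="session")
def det_burst_trace():
    """Deterministic run at g_BK = 1 nS (pure bursting)."""
    cfg = SimulationConfig(duration=8000.0, noise=NoiseFlags.none(),
                           transient_discard=1000.0, record_stride=5)
    return simulate(DEFAULT_PARAMS.with_total_conductance("BK", 1.0), cfg)
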