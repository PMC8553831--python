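import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from evoweb import Parameters, Species
from evoweb.experiment import desk_config, run_simulation, run_sweep


@pytest.fixture
def params() -> Parameters:
    return Parameters()


@pytest.fixture
def ancestor() -> Species:
    return Species(id=0, m=100.0, f=1.0, s=0.4, origin="ancestor")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scaled_run():
    """One scaled-down high-strangeness run shared by the structural checks."""
    return run_simulation(desk_config(5.0, horizon=100_000.0), seed=2)


@pytest.fixture(scope="session")
def sweep_records():
    """Desk-scale invader-strangeness sweep: 10 z values on [0.5, 5.0],
    3 replicates each, horizon 2e5."""
    grid = np.linspace(0.5, 5.0, 10)
    return run_sweep(grid, 3, config_factory=lambda z: desk_config(z), base_seed=0)
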