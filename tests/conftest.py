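import numpy as np
import pytest

from tcquant import emt_sim


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim_result():
    """One default-condition cycle-1 simulation shared across tests."""
    cfg = emt_sim.SimulationConfig(seed=11, n_cycles=1)
    return emt_sim.run_simulation(cfg)


@pytest.fixture(scope="session")
def sim_snapshot(sim_result):
    return sim_result.snapshots[0]


@pytest.fixture(scope="session")
def attractors():
    return emt_sim.steady_states(emt_sim.default_network(), n_grid=300, seed=1)
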