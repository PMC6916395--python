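import numpy as np
import pytest

from jmie import JointModel, SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated study shared across tests (scenario 1)."""
    return simulate_study(SimulationConfig(n_subjects=120), seed=7)


@pytest.fixture(scope="session")
def fitted_small(sim_small):
    """A quick single-chain joint-model fit for prediction-level tests."""
    return JointModel(n_chains=1, n_warmup=400, n_draws=400, seed=2).fit(
        sim_small.study)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
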