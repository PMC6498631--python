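import numpy as np
import pytest

from sgcurve import MCMCConfig, PriorSpec, SimulationConfig, simulate_sgc_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-animal synthetic study shared by the cheaper sampler tests."""
    cfg = SimulationConfig(n_animals=60, n_sires=6)
    data, truth = simulate_sgc_dataset(cfg, np.random.default_rng(101))
    return data, truth


@pytest.fixture
def short_config():
    return MCMCConfig(iterations=400, burn_in=200, thin=2, n_chains=1, seed=7)


@pytest.fixture
def vague_priors():
    pri = PriorSpec.preliminary()
    pri.S_u = np.eye(4)
    return pri
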