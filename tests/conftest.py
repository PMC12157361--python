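import numpy as np
import pytest

from circlescan.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimulationConfig(
        n_samples=30,
        logr_noise_sd=0.0,
        n_background_sv=0,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_cfg):
    return simulate_cohort(noiseless_cfg)
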