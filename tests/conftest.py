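import numpy as np
import pytest

from mcdcontrol.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """Six simulated subjects with the default design (74 trials each)."""
    cfg = SimConfig(n_subjects=6, seed=424242)
    trials, truth = simulate_experiment(cfg)
    return cfg, trials, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
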