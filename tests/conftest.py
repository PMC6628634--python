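import numpy as np
import pytest

from mdmcpt import CPTParams, TaskConfig, generate_task


@pytest.fixture(scope="session")
def task():
    """Default 126-trial task, shared across tests."""
    return generate_task(0)


@pytest.fixture(scope="session")
def small_task():
    """Reduced 42-trial task used by heavier Monte-Carlo checks."""
    cfg = TaskConfig(n_trials=42, n_per_type=14, n_equal_prob=6,
                     n_equal_prob_gain=2, n_equal_prob_loss=2,
                     n_equal_prob_mixed=2)
    return generate_task(1, cfg)


@pytest.fixture()
def identity_params():
    return CPTParams()


@pytest.fixture()
def typical_params():
    return CPTParams(alpha=0.85, lam=1.25, gamma=0.7, delta=0.9)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
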