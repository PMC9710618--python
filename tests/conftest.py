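import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def trimer_dataset():
    """One deterministic synthetic M/D/T dataset at benchmark scale."""
    from blinkmix import SimulationConfig, simulate_dataset

    config = SimulationConfig(
        true_weights=(0.4, 0.4, 0.2), lam=3.6, theta=1.0,
        n_complexes=1000, seed=99,
    )
    return simulate_dataset(config)
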