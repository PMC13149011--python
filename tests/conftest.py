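import numpy as np
import pytest

from copsim.transmission import SimConfig, run_simulation


def small_config(**overrides) -> SimConfig:
    """A 5,000-agent short-horizon configuration for fast unit tests.

    gamma = R0/(N * t_infectious) scales with N, so the epidemic's
    per-capita dynamics mirror the full-size run.
    """
    params = dict(
        N=5_000,
        initial_naive_S=4_850,
        initial_prior_exposure_S=100,
        initial_E=25,
        initial_infectious=25,
        horizon=120,
        record_interval=10,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def history_s1():
    """One full-size scenario-1 epidemic shared across tests."""
    return run_simulation(SimConfig(), "linear", rng=7)


@pytest.fixture(scope="session")
def history_s2():
    """One full-size scenario-2 (20% high-risk) epidemic."""
    return run_simulation(SimConfig(p_high_risk=0.2), "linear", rng=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
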