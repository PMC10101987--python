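import numpy as np
import pytest

from cllscreen import DEFAULT_SERIES, SimScreenConfig, simulate_screen


@pytest.fixture(scope="session")
def series():
    return DEFAULT_SERIES


@pytest.fixture(scope="session")
def small_screen():
    """A small noisy screen shared across tests (10 singles, 5 combos)."""
    return simulate_screen(SimScreenConfig(seed=123, n_singles=10, n_combos=5))


@pytest.fixture(scope="session")
def clean_screen():
    """Noiseless screen: normalization must recover the truth exactly."""
    return simulate_screen(
        SimScreenConfig(
            seed=5, n_singles=8, n_combos=4, noise_cv=0.0,
            sigma_neg=0.0, sigma_pos=0.0,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
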