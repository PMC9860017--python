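import numpy as np
import pytest

from genarch import simulate as sim


@pytest.fixture(scope="session")
def small_panel():
    """Small LD-blocked panel shared by fast unit tests."""
    return sim.simulate_ld_panel(600, 60, block_size=6, rho=(0.0, 0.8), seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_correlation(rng, m, jitter=1e-9):
    """Random well-conditioned correlation matrix."""
    a = rng.standard_normal((m, m + 5))
    s = a @ a.T + jitter * np.eye(m)
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)
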