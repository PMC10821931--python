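import numpy as np
import pytest

from blinkmux.changepoint import estimate_critical_values


@pytest.fixture(scope="session")
def crit_table():
    """Shared Monte-Carlo critical-value table (alpha = 0.05)."""
    return estimate_critical_values(
        [8, 16, 32, 64, 128, 256, 512, 1024],
        alpha=0.05,
        n_replicates=2000,
        rng_seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
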