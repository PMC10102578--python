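import numpy as np
import pytest

from breathsig import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort reused by read-only tests."""
    cfg = sd.SimConfig(
        n_case=15, n_control=15, n_features=120, n_differential=20, rng_seed=42
    )
    return sd.simulate_cohort(cfg)
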