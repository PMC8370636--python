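import numpy as np
import pytest

from twinpath.config import default_config
from twinpath.simulate import apply_missingness, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Fully observed cohort of 1,500 families (fast, reused across tests)."""
    cfg = default_config(seed=42, n_families=1500)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_missing(small_cohort):
    cfg, data = small_cohort
    return cfg, apply_missingness(data, cfg)


@pytest.fixture(scope="session")
def big_cohort():
    """Larger cohort for moment-calibration checks."""
    cfg = default_config(seed=7, n_families=8000)
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
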