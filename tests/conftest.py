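import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("default")

from censimpute import (  # noqa: E402
    CensoredDataset,
    LognormalParams,
    MeasurementRange,
    PrecisionProfile,
    censor,
    measure,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def default_range():
    return MeasurementRange(0.0, 400.0)


@pytest.fixture
def simulated_dataset(rng):
    """Lognormal(ln 100, 0.5) sample of 500, noisy, censored at (60, 250)."""
    truth = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=500)
    profile = PrecisionProfile(cv_base=0.05, k_low=0.5, k_high=1e-4)
    measured = measure(truth, profile, seed=rng)
    return censor(measured, 60.0, 250.0, true_values=truth)


@pytest.fixture
def uncensored_dataset(rng):
    """A dataset whose cutoffs censor nothing (both censored counts zero)."""
    values = rng.lognormal(mean=np.log(100.0), sigma=0.4, size=300)
    return CensoredDataset(
        observed=values, n_bc=0, n_ac=0, lc=values.min() - 1.0, uc=values.max() + 1.0
    )
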