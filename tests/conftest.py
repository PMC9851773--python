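import numpy as np
import pytest

from dtwconnect import RoiTimeseries, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Reduced-size generator config for fast unit tests."""
    return SimConfig(n_subjects=4, n_regions=8, n_volumes=120, seed=7)


@pytest.fixture
def random_timeseries(rng):
    """A plain random T x R timeseries riding on a positive baseline."""
    values = 100.0 + rng.normal(0.0, 1.0, (120, 6))
    return RoiTimeseries(values, tr_seconds=2.0)
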