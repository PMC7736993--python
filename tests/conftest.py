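import numpy as np
import pytest

import dfckit as dk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ts(rng):
    """Stationary 5-region, 200-sample Gaussian series."""
    return dk.gen_stationary_gaussian(5, 200, seed=101)


@pytest.fixture
def small_stream(small_ts):
    """Non-overlapping 6-frame stream of the small fixture."""
    return dk.compute_dfc_stream(small_ts, dk.StreamConfig(30, 30))


@pytest.fixture
def smooth_stream(small_ts):
    """Maximally smooth (step-1) stream of the small fixture."""
    return dk.compute_dfc_stream(small_ts, dk.StreamConfig(30, 1))


def pearson_oracle(x, y):
    """Textbook Pearson correlation: sums-of-products form."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx = (x * x).sum()
    syy = (y * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt(n * sxx - sx * sx) * np.sqrt(n * syy - sy * sy)
    return num / den
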