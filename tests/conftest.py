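import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dfcgene as d

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20231203)


@pytest.fixture
def region_table5():
    return d.RegionTable.synthetic(5)


@pytest.fixture
def small_ts(rng, region_table5):
    """Well-behaved 5-region, 60-timepoint subject."""
    data = rng.standard_normal((5, 60))
    return d.RegionalTimeSeriesSet("sub", "HC", data, region_table5)


def random_network(n, rng, density=0.6, region_table=None):
    """Random symmetric thresholded-correlation-like network."""
    r = np.corrcoef(rng.standard_normal((n, 3 * n)))
    mask = rng.random((n, n)) < density
    mask = mask & mask.T
    np.fill_diagonal(mask, False)
    np.fill_diagonal(r, 0.0)
    r = 0.5 * (r + r.T)
    return d.FunctionalNetwork(np.where(mask, r, 0.0), mask, 0.01, region_table)


@pytest.fixture
def random_net(rng):
    return random_network(12, rng)
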