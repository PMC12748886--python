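import logging

import numpy as np
import pytest

from heatattrib.synthetic import WorldConfig, simulate_world

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by integration-style tests."""
    return simulate_world(WorldConfig(n_cities=4), seed=20260924)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
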