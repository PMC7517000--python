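import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def star5_edges():
    """Star on 5 nodes, hub = 0."""
    return 5, np.array([(0, i) for i in range(1, 5)])


@pytest.fixture
def path_edges():
    def make(n):
        return n, np.array([(i, i + 1) for i in range(n - 1)])
    return make
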