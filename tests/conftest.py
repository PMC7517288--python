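import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_hypergraph():
    """One triangle and two links on 6 vertices (simple, rank 3)."""
    from hyperpgg import Hypergraph

    return Hypergraph(6, ((0, 1, 2), (2, 3), (4, 5)))
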