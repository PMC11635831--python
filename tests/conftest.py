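import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def training_foods():
    from homeoforage import make_training_foods

    return make_training_foods()


@pytest.fixture
def fast_arena():
    """Arena without rangefinder computation, for privileged-state policies."""
    from homeoforage import ArenaConfig

    return ArenaConfig(compute_extero=False)
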