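import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import octavg as og

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """A quick-to-render healthy eye used by several suites."""
    return og.healthy_spec(image_side=150, seed=11, noise_sd=12.0)


@pytest.fixture(scope="session")
def small_stack(small_spec):
    return og.generate_stack(small_spec)


@pytest.fixture(scope="session")
def registered_small(small_stack):
    stack, gt = small_stack
    return og.register_stack(stack), gt


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
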