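import numpy as np
import pytest

from rotorelax.pipeline import demo_phantom_spec
from rotorelax.synth import default_cohort_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """Compact 32 x 32 x 20 phantom spec shared across tests."""
    return demo_phantom_spec()


@pytest.fixture(scope="session")
def small_labels(small_phantom):
    return small_phantom.rasterize()


@pytest.fixture(scope="session")
def control_cohort():
    return default_cohort_spec(seed=7)
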