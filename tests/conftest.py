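import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from qcart import datasets
from qcart.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def protocols():
    return datasets.cohort_protocols()


@pytest.fixture(scope="session")
def week5_phantom():
    """Small week-5 phantom (48 x 48) shared across fitting tests."""
    spec = PhantomSpec.for_week(5, shape=(48, 48))
    return make_phantom(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231106)
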