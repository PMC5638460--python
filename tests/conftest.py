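import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_basis():
    from hemolig.synthetic import make_reference_basis

    return make_reference_basis()


@pytest.fixture(scope="session")
def hb1_stripped():
    from hemolig.synthetic import PRESETS

    return PRESETS["hb1_stripped"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
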