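import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nirspain.montage import build_montage
from nirspain.paradigm import make_paradigm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def montage():
    return build_montage()


@pytest.fixture(scope="session")
def paradigm():
    return make_paradigm()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
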