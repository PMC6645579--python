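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
    return np.random.default_rng(20260929)


@pytest.fixture
def default_params():
    from pytva.core import TVAParams

    return TVAParams.from_expected_K(3.5, 50.0, 15.0, 0.5, 0.4)
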