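import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "caparch",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("caparch")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
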