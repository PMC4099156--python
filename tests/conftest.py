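import pytest
from hypothesis import HealthCheck, settings

from mcrpcsim import builtin_model

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def current_spec():
    return builtin_model("current")


@pytest.fixture(scope="session")
def alternate_spec():
    return builtin_model("alternate")
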