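import pytest
from hypothesis import HealthCheck, settings

from ratioamp.degradation_sim import default_panel, default_pool

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def pool():
    return default_pool()
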