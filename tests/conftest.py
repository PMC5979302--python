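import pytest
from hypothesis import HealthCheck, settings

from ampcnv.dosage import default_maq_panel, default_mlpa_panel
from ampcnv.panel import default_panel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def maq_panel():
    return default_maq_panel()


@pytest.fixture(scope="session")
def mlpa_panel():
    return default_mlpa_panel()
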