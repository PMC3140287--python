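import pytest
from hypothesis import HealthCheck, settings

from thromboflap import ScreeningModel, datasets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel():
    return datasets.load_panel()


@pytest.fixture(scope="session")
def params():
    return datasets.load_params()


@pytest.fixture(scope="session")
def results(panel, params):
    """Fitted model on the packaged institutional fixtures."""
    return ScreeningModel(panel, params).fit()


@pytest.fixture(scope="session")
def registry_records():
    return datasets.load_registry()


@pytest.fixture(scope="session")
def cost_pairs():
    return datasets.load_cost_pairs()
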