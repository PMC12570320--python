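import pytest
from hypothesis import settings, HealthCheck

from screencea.params import load_fixture
from screencea.disease import calibrate_hazards
from screencea.engine import run_cea

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def smoking_params():
    return load_fixture("smoking")


@pytest.fixture(scope="session")
def nonsmoking_params():
    return load_fixture("nonsmoking")


@pytest.fixture(scope="session")
def smoking_hazards(smoking_params):
    return calibrate_hazards(smoking_params.survival)


@pytest.fixture(scope="session")
def base_cea(smoking_params, nonsmoking_params):
    """Base-case CEA results for both cohorts (computed once per session)."""
    return {
        "smoking": run_cea(smoking_params),
        "nonsmoking": run_cea(nonsmoking_params),
    }
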