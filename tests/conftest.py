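import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

warnings.filterwarnings(
    "ignore", message=".*force_all_finite.*", category=FutureWarning
)


@pytest.fixture(scope="session")
def epad_raw():
    """Small raw clinical-cohort fixture shared across tests."""
    from synthqc.fixtures import FixtureConfig, generate_epad_like

    return generate_epad_like(FixtureConfig(n=400, seed=42))


@pytest.fixture(scope="session")
def epad_clean(epad_raw):
    """Preprocessed (analysis-schema) version of the shared fixture."""
    from synthqc.preprocess import preprocess_epad

    return preprocess_epad(epad_raw)
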