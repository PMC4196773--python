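import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mfari.index import Config, fit_standardisation
from mfari.tiecks import generate_templates

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def templates():
    """The 91 spline-interpolated model step responses (5 Hz, ideal step)."""
    return generate_templates()


@pytest.fixture(scope="session")
def std_model(templates):
    """Standardisation regression refitted on the session template set."""
    return fit_standardisation(templates, Config())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
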