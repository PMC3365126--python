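import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prestinmem.parameters import default_ohc_params, default_sphere_params

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def ohc():
    return default_ohc_params()


@pytest.fixture
def sphere():
    return default_sphere_params()


@pytest.fixture
def t_grid():
    """Coarse strictly-positive time grid spanning several tau_e."""
    return np.linspace(2e-6, 5e-5, 12)


@pytest.fixture
def band_omega():
    """Log-spaced angular frequencies over the 1-80 kHz acoustic band."""
    return 2 * np.pi * np.logspace(3, np.log10(8e4), 120)
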