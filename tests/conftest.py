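import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=20,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fine_grid_k():
    """2 K temperature grid over the full cryostat range."""
    return np.arange(100.0, 381.0, 2.0)


@pytest.fixture(scope="session")
def coarse_grid_k():
    """10 K increments, the typical heating protocol."""
    return np.arange(100.0, 381.0, 10.0)


@pytest.fixture(scope="session")
def amide_grid_cm():
    """Wavenumber grid with margin around the amide I window."""
    return np.arange(1580.0, 1721.0, 1.0)
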