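import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

from pcnir import SpectraMatrix, scaled_config, simulate_dataset  # noqa: E402


@pytest.fixture
def tiny_spectra():
    """3 samples x 5 wavenumbers with easily checked values."""
    wn = np.array([4000.0, 4008.0, 4016.0, 4024.0, 4032.0])
    block = np.array([[0.1, 0.2, 0.3, 0.4, 0.5],
                      [0.5, 0.4, 0.3, 0.2, 0.1],
                      [0.2, 0.2, 0.4, 0.2, 0.2]])
    return SpectraMatrix(wn, block, ["A", "B", "C"])


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic dataset shared by the slower unit tests."""
    return simulate_dataset(scaled_config(seed=0))
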