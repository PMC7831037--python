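import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wheatlnc.io import Spectrum
from wheatlnc.synthetic import canopy_spectrum, make_dataset, params_from_lnc

settings.register_profile(
    "ci", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def canopy_spectrum_mid():
    """Noise-free canopy spectrum at a mid-range LNC (3% dry mass)."""
    return canopy_spectrum(params_from_lnc(3.0))


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset shared across fast tests."""
    return make_dataset(n=20, seed=7, patch_size=16)


@pytest.fixture()
def v_spectrum():
    """The hand-checkable V-shaped absorption spectrum on a 100 nm grid."""
    return Spectrum(wavelengths=np.array([500.0, 600.0, 700.0]),
                    reflectance=np.array([0.4, 0.2, 0.4]))
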