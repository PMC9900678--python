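import numpy as np
import pytest

from dotrecon.forward import AcquisitionConfig
from dotrecon.optics import OpticalProperties
from dotrecon.phantoms import Inclusion, PhantomSpec


@pytest.fixture(scope="session")
def background():
    return OpticalProperties(0.01, 1.0)


@pytest.fixture(scope="session")
def homogeneous_spec(background):
    """60 mm homogeneous phantom at 50 MHz."""
    return PhantomSpec(60.0, 50.0, background)


@pytest.fixture(scope="session")
def inclusion_spec(background):
    """60 mm phantom with one absorbing/scattering inclusion off-centre."""
    inc = Inclusion((8.0, 5.0), 7.0, OpticalProperties(0.02, 2.0))
    return PhantomSpec(60.0, 50.0, background, (inc,))


@pytest.fixture(scope="session")
def acq16():
    return AcquisitionConfig(n_sources=16, noise_level=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
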