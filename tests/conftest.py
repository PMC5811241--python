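import numpy as np
import pytest

from fibermito.orientation import build_gabor_bank


@pytest.fixture(scope="session")
def gabor_bank():
    return build_gabor_bank()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_stripes(shape=(160, 160), angle_deg=60.0, wavelength=12.0):
    """Sinusoidal grating whose stripes run along ``angle_deg``."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    phi = np.deg2rad(angle_deg + 90.0)  # wave vector perpendicular to stripes
    u = xx * np.cos(phi) + yy * np.sin(phi)
    return 0.5 + 0.5 * np.cos(2 * np.pi * u / wavelength)
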