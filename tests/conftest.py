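import numpy as np
import pytest

from llstorm import AcquisitionGeometry, AstigCalibration
from llstorm.localize import _pixel_profile


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def geometry():
    """Full-scale acquisition geometry (printed instrument parameters)."""
    return AcquisitionGeometry(n_stacks=573)


@pytest.fixture(scope="session")
def calibration():
    """Astigmatic defocus calibration from the standard model."""
    return AstigCalibration.from_defocus_model()


def render_spot(n, cx, cy, sx, sy, photons, background):
    """Pixel-integrated elliptical Gaussian ROI (noise-free expectation).

    Independent of fit_spot's optimizer; shares only the pixel-integration
    primitive so rendered and fitted models agree on pixel conventions.
    """
    Ex = _pixel_profile(n, cx, sx)[0]
    Ey = _pixel_profile(n, cy, sy)[0]
    return photons * np.outer(Ey, Ex) + background
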