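import numpy as np
import pytest

from mesoquant import CalibratedImage, PolylineROI


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ring_image():
    """Concentric Gaussian ring: peak radius 25 um, radial sigma 1 um."""
    ps = 0.2
    n = 400
    y, x = np.mgrid[0:n, 0:n] * ps
    c = (n - 1) * ps / 2.0
    r = np.hypot(x - c, y - c)
    pixels = 100.0 * np.exp(-((r - 25.0) ** 2) / 2.0)
    return CalibratedImage(pixels, ps, "ring"), c


@pytest.fixture
def semicircle_roi(ring_image):
    _, c = ring_image
    th = np.linspace(0.0, np.pi, 200)
    pts = np.column_stack([c + 25.0 * np.cos(th), c + 25.0 * np.sin(th)])
    return PolylineROI(pts)
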