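import numpy as np
import pytest

from synaptoquant.linescan import LineScanProfile


def gaussian_trace(centers, amplitude=6.0, background=2.0, sigma=0.3,
                   length=20.0, pixel=0.1):
    """Noiseless trace of Gaussian bumps on a flat background."""
    x = np.arange(int(round(length / pixel)) + 1) * pixel
    y = np.full_like(x, background)
    for c in np.atleast_1d(centers):
        y = y + amplitude * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    return LineScanProfile(positions=x, intensities=y, pixel_size=pixel)


@pytest.fixture
def punctate_trace():
    """Five well-separated identical puncta: peaks B+A, troughs B."""
    return gaussian_trace(centers=[3, 6.5, 10, 13.5, 17])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
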