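import numpy as np
import pytest

from wormfreq.simulate import WormSimConfig, render_worm_video


@pytest.fixture(scope="session")
def worm_video():
    """A short clean 1 Hz swimming video shared across tests (seeded)."""
    stack, truth = render_worm_video(WormSimConfig(f0=1.0, seed=2, duration_s=6.0))
    return stack, truth


@pytest.fixture(scope="session")
def gaussian_blob():
    """A smooth anisotropic blob for invariance tests (no symmetry axes)."""
    yy, xx = np.mgrid[0:96, 0:96].astype(np.float64)
    g1 = np.exp(-(((yy - 44) / 10.0) ** 2 + ((xx - 50) / 16.0) ** 2))
    g2 = 0.6 * np.exp(-(((yy - 58) / 6.0) ** 2 + ((xx - 38) / 7.0) ** 2))
    return 100.0 * (g1 + g2)
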