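import numpy as np
import pytest

from neurotoxiscore.images import ChannelImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def bimodal_image(rng):
    """1000-pixel image from two well-separated Gaussians (means 50/200)."""
    vals = np.concatenate([rng.normal(50, 10, 500), rng.normal(200, 10, 500)])
    return ChannelImage(np.clip(vals, 0, None).reshape(25, 40))


@pytest.fixture
def disk_image():
    """Bright disk (radius 20, intensity 200) on a dark background (20)."""
    yy, xx = np.mgrid[0:128, 0:128]
    disk = (yy - 64) ** 2 + (xx - 64) ** 2 <= 20 ** 2
    img = np.where(disk, 200.0, 20.0)
    return ChannelImage(img), disk
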