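import numpy as np
import pytest

from foveastrain.eye_image import EyeFrame


def make_disk_frame(
    size: tuple[int, int] = (200, 200),
    center: tuple[float, float] = (100.0, 100.0),
    radius: float = 30.0,
    disk_gray: float = 20.0,
    bg_gray: float = 200.0,
) -> np.ndarray:
    """Hard-edged dark disk on a bright background (no anti-aliasing)."""
    h, w = size
    img = np.full((h, w), bg_gray)
    yy, xx = np.mgrid[0:h, 0:w]
    img[np.hypot(xx - center[0], yy - center[1]) <= radius] = disk_gray
    return img


@pytest.fixture
def disk_frame() -> EyeFrame:
    return EyeFrame(make_disk_frame().astype(np.uint8))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
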