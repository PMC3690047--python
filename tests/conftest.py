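import numpy as np
import pytest

from fruitglove.vision import CameraModel


@pytest.fixture(scope="session")
def small_camera() -> CameraModel:
    """A 160x120 wide-angle camera that keeps segmentation tests fast."""
    return CameraModel.from_fov(160, 120, 120.0, 2.5)


@pytest.fixture()
def textured_frame() -> np.ndarray:
    """A smooth random-texture grayscale frame for flow/disparity tests."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(42)
    return gaussian_filter(rng.uniform(0, 255, (120, 160)), 2.0)
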