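import numpy as np
import pytest

from salixmap import CameraModel


@pytest.fixture
def camera() -> CameraModel:
    """Default rig geometry (1280x720, 87x58 deg FOV, 28.5 deg tilt)."""
    return CameraModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
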