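import numpy as np
import pytest

from endoview.benchmark import generate_two_camera_scene


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()


@pytest.fixture(scope="session")
def scene():
    """One shared synthetic two-camera scene (noise-free)."""
    return generate_two_camera_scene(7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
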