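import numpy as np
import pytest

from acukit import fixtures
from acukit.types import Keypoint, KeypointSet

#: 5-marker 128 x 128 layout used by the restoration-quality suite.
SMALL_POSITIONS = {
    "A": (30.0, 30.0),
    "B": (90.0, 40.0),
    "C": (50.0, 90.0),
    "D": (95.0, 95.0),
    "E": (30.0, 70.0),
}


def small_spec(seed: int = 0) -> fixtures.FixtureSpec:
    return fixtures.FixtureSpec(
        width=128, height=128, keypoint_positions=SMALL_POSITIONS,
        marker_radius=6, seed=seed,
    )


@pytest.fixture
def small_image():
    return fixtures.make_back_image(small_spec(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_keypoints():
    return KeypointSet({
        "P1": Keypoint(10.0, 10.0),
        "P2": Keypoint(50.0, 10.0),
        "P3": Keypoint(50.0, 50.0),
        "P4": Keypoint(10.0, 50.0),
    })
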