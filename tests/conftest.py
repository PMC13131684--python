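import numpy as np
import pytest

from mveks.geometry import CameraModel, CameraRig
from mveks.synthetic import make_rig


@pytest.fixture
def identity_camera():
    """Pinhole at the world origin looking down +z, no distortion."""
    return CameraModel(
        name="ident", focal=(100.0, 100.0), principal=(50.0, 50.0)
    )


@pytest.fixture
def ring_rig():
    """Three distortion-free cameras on a circle looking at the origin."""
    return make_rig(n_views=3, radius=5.0, focal=300.0)


@pytest.fixture
def distorted_rig():
    return make_rig(n_views=3, radius=5.0, focal=300.0, distortion_level=0.5)


def random_camera(rng, distortion=True):
    """A random plausible camera; distortion coefficients in the moderate
    range the undistortion contract covers."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_rotvec()
    dist = (
        (
            rng.uniform(-0.3, 0.3),
            rng.uniform(-0.1, 0.1),
            rng.uniform(-0.01, 0.01),
            rng.uniform(-0.01, 0.01),
            rng.uniform(-0.02, 0.02),
        )
        if distortion
        else (0.0,) * 5
    )
    return CameraModel(
        name="rand",
        focal=(rng.uniform(200, 800), rng.uniform(200, 800)),
        principal=(rng.uniform(200, 400), rng.uniform(150, 300)),
        distortion=dist,
        rotation=tuple(rot),
        translation=tuple(rng.uniform(-1, 1, 3)),
    )
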