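import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_scene(rng, width=16, height=12, channels=3):
    """Random texture, positive depth, small motion, plausible intrinsics."""
    from endosfm.geometry import Intrinsics, RigidMotion
    img = rng.random((height, width, channels))
    depth = 1.0 + rng.random((height, width))
    motion = RigidMotion(tuple(rng.normal(scale=0.02, size=3)),
                         tuple(rng.normal(scale=0.02, size=3)))
    intr = Intrinsics(fx=0.6 + 0.6 * rng.random(),
                      fy=0.6 + 0.6 * rng.random(),
                      cx=0.4 + 0.2 * rng.random(),
                      cy=0.4 + 0.2 * rng.random())
    return img, depth, motion, intr
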