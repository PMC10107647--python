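import numpy as np
import pytest

from lmreg3d import EulerAngles, PointSet, rotation_matrix, transform_points


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


def random_angles(rng) -> EulerAngles:
    return EulerAngles(*rng.uniform(-np.pi, np.pi, 3))


def rigid_pair(rng, n=7, box=100.0, angles=None, translation=None):
    """A point set and its exact rigid transform, with the ground truth.

    Returns (first, second, angles) where second = R (first - c) + c + t.
    """
    first = PointSet.from_coords(rng.uniform(0, box, (n, 3)))
    if angles is None:
        angles = random_angles(rng)
    if translation is None:
        translation = rng.uniform(-box / 4, box / 4, 3)
    c = first.centroid
    second = transform_points(first, angles, c, c + translation)
    return first, second, angles


@pytest.fixture
def rigid_pair_factory(rng):
    def make(**kw):
        return rigid_pair(rng, **kw)

    return make
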