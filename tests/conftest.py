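"""Shared fixtures and random generators for the test suite."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sacronav import LandmarkSet, PhantomParams, SimilarityTransform, Trajectory, make_phantom


def random_landmarks(rng, spread=120.0, min_area=500.0) -> LandmarkSet:
    """A random, well-conditioned landmark triangle."""
    while True:
        pts = rng.uniform(-spread, spread, size=(3, 3))
        try:
            lm = LandmarkSet.from_array(pts)
        except ValueError:
            continue
        if lm.triangle_area() >= min_area:
            return lm


def random_similarity(rng, scale_range=(0.7, 1.4), translation=200.0) -> SimilarityTransform:
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-translation, translation, size=3)
    s = rng.uniform(*scale_range)
    return SimilarityTransform(R, t, s)


def random_trajectory(rng, box=150.0, diameter_range=(4.0, 9.0), depth_range=(40.0, 120.0)) -> Trajectory:
    entry = rng.uniform(-box, box, size=3)
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    depth = rng.uniform(*depth_range)
    aim = entry + rng.uniform(0.5, 1.2) * depth * d
    return Trajectory(entry, aim, rng.uniform(*diameter_range), depth)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(PhantomParams())
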