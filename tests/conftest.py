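import numpy as np
import pytest

from slnav.geometry import PointCloud
from slnav.phantom import PhantomSpec, make_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_scene():
    """Full 7-vertebra phantom, seed 1."""
    return make_scene(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def tiny_scene():
    """Small 2-vertebra phantom for cheap pipeline tests."""
    return make_scene(PhantomSpec(seed=3, n_vertebrae=2))


def cylinder_surface_points(rng, n, arc_deg, sigma, axis_point, direction,
                            radius=12.5, length=150.0):
    """Sample a cylinder's lateral surface over a given visible arc, with
    optional radial Gaussian noise."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0]) if abs(direction[0]) < 0.9 \
        else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    ang = np.radians(rng.uniform(-arc_deg / 2.0, arc_deg / 2.0, n))
    z = rng.uniform(-length / 2.0, length / 2.0, n)
    radial = np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2
    pts = np.asarray(axis_point) + z[:, None] * direction + radius * radial
    if sigma > 0:
        pts = pts + rng.normal(0.0, sigma, n)[:, None] * radial
    return PointCloud(pts)
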