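import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tripoint import ImplantPose, LandmarkPair, Point3


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rigid(rng):
    """A random rotation matrix and translation vector."""
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-30, 30, size=3)
    return rot, trans


def random_triple(rng, space="P", min_sin=0.1, scale=30.0):
    """Three noncollinear points in one space."""
    while True:
        pts = rng.uniform(-scale, scale, size=(3, 3))
        ab, ac = pts[1] - pts[0], pts[2] - pts[0]
        denom = np.linalg.norm(ab) * np.linalg.norm(ac)
        if denom > 1e-6 and np.linalg.norm(np.cross(ab, ac)) / denom >= min_sin:
            return [Point3.from_array(p, space=space) for p in pts]


def rigid_pairs(points_p, rot, trans, labels=None):
    """Exact landmark pairs relating P coordinates to their rigid image."""
    labels = labels or [f"L{i + 1}" for i in range(len(points_p))]
    pairs = []
    for label, p in zip(labels, points_p):
        r = rot @ np.asarray(p, dtype=float) + trans
        pairs.append(
            LandmarkPair(
                label=label,
                p=Point3.from_array(p, space="P"),
                r=Point3.from_array(r, space="R"),
            )
        )
    return pairs


def make_pose(coronal, apical, space="P"):
    return ImplantPose(
        coronal=Point3.from_array(coronal, space=space),
        apical=Point3.from_array(apical, space=space),
    )
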