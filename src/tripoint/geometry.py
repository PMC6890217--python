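"""Relative orthonormal coordinate frames built from three noncollinear points.

A frame places its origin at the first point ``A``, its X axis along ``AB``,
its Y axis in the ``ABC`` plane on the ``C`` side, and its Z axis along the
plane normal ``AB x AC``.  Both image spaces are framed with the same rule, so
expressing each space in its own frame yields a shared, comparable system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "Point3",
    "Frame",
    "build_frame",
    "to_frame_coords",
    "from_frame_coords",
    "DEFAULT_COLLINEARITY_TOL",
]

#: Lower bound on sin(angle CAB); far below any usable anatomical triple.
DEFAULT_COLLINEARITY_TOL = 1e-6

#: Tag of the common system produced by frame transformation.
COMMON_SPACE = "N"


@dataclass(frozen=True)
class Point3:
    """A 3-D coordinate in millimetres, tagged with its image space."""

    x: float
    y: float
    z: float
    space: str = "P"

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValueError(f"non-finite coordinate in {self!r}")

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a, space: str = "P") -> "Point3":
        x, y, z = (float(v) for v in a)
        return cls(x, y, z, space)

    def distance_to(self, other: "Point3") -> float:
        return float(np.linalg.norm(self.to_array() - other.to_array()))


@dataclass(frozen=True)
class Frame:
    """Origin plus right-handed orthonormal axes defining a relative system."""

    origin: Point3
    axis_x: np.ndarray
    axis_y: np.ndarray
    axis_z: np.ndarray
    target_space: str = COMMON_SPACE

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose rows are the axis unit vectors."""
        return np.vstack([self.axis_x, self.axis_y, self.axis_z])


def build_frame(
    A: Point3,
    B: Point3,
    C: Point3,
    collinearity_tol: float = DEFAULT_COLLINEARITY_TOL,
) -> Frame:
    """Construct the relative frame from three noncollinear points.

    Parameters
    ----------
    A, B, C:
        Points sharing one image space.  ``A`` becomes the origin, ``AB`` the
        X direction, and ``C`` fixes the XY plane (Y on the ``C`` side).
    collinearity_tol:
        Minimum allowed ``sin(angle CAB)``.

    Raises
    ------
    DegenerateGeometryError
        If points coincide or are collinear beyond tolerance.
    ValueError
        If the points do not share a space tag.
    """
    if not (A.space == B.space == C.space):
        raise ValueError(
            f"frame points must share one space, got {A.space}/{B.space}/{C.space}"
        )
    a, b, c = A.to_array(), B.to_array(), C.to_array()
    ab = b - a
    ac = c - a
    nab = np.linalg.norm(ab)
    nac = np.linalg.norm(ac)
    if nab == 0.0 or nac == 0.0:
        raise DegenerateGeometryError("coincident frame points")

    normal = np.cross(ab, ac)
    sin_cab = np.linalg.norm(normal) / (nab * nac)
    if sin_cab < collinearity_tol:
        raise DegenerateGeometryError(
            f"collinear frame points (sin angle {sin_cab:.3e} < {collinearity_tol:.3e})"
        )

    x_hat = ab / nab
    # Vector rejection of AC from the X axis keeps Y in plane ABC on C's side.
    ac_y = ac - np.dot(ac, x_hat) * x_hat
    y_hat = ac_y / np.linalg.norm(ac_y)
    z_hat = normal / np.linalg.norm(normal)
    return Frame(origin=A, axis_x=x_hat, axis_y=y_hat, axis_z=z_hat)


def to_frame_coords(G: Point3, frame: Frame) -> Point3:
    """Express ``G`` in the frame's coordinate system.

    The axes are orthonormal, so the solution of
    ``AG = X'*x + Y'*y + Z'*z`` is the projection of ``G - origin`` onto
    each axis.
    """
    if G.space != frame.origin.space:
        raise ValueError(
            f"point space {G.space!r} does not match frame space {frame.origin.space!r}"
        )
    v = frame.rotation @ (G.to_array() - frame.origin.to_array())
    return Point3.from_array(v, space=frame.target_space)


def from_frame_coords(G_prime: Point3, frame: Frame) -> Point3:
    """Inverse of :func:`to_frame_coords`: map frame coordinates back."""
    if G_prime.space != frame.target_space:
        raise ValueError(
            f"point space {G_prime.space!r} is not the frame target "
            f"{frame.target_space!r}"
        )
    v = frame.origin.to_array() + frame.rotation.T @ G_prime.to_array()
    return Point3.from_array(v, space=frame.origin.space)
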