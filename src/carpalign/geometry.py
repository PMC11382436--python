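"""Shared vector geometry: axes, rotations, line fits.

World coordinate convention used throughout the package:

* ``x`` — radioulnar,
* ``y`` — dorsopalmar, palmar positive,
* ``z`` — proximodistal, distal positive.

Flexion (palmar angulation of the distal bone) is the positive angle
direction in the lateral plane.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Axis3D",
    "rot_flexion",
    "rotation_about_axis",
    "random_rotation",
    "tls_line_fit",
    "wrap_angle_deg",
    "unit",
]

_UNIT_TOL = 1e-9


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` normalized to unit length; raise on a near-zero vector."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a near-zero vector")
    return v / n


@dataclass(frozen=True)
class Axis3D:
    """A 3D line given by a point (mm) and a unit direction.

    Directions are oriented proximal-to-distal whenever that notion is
    defined (positive component along the proximodistal reference).
    """

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-6:
            if n < 1e-12:
                raise ValueError("Axis3D direction must be nonzero")
            d = d / n
        else:
            d = d / n  # tighten to exact unit length
        object.__setattr__(self, "direction", d)
        if abs(np.linalg.norm(self.direction) - 1.0) > _UNIT_TOL:
            raise ValueError("Axis3D direction failed to normalize")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray = None) -> "Axis3D":
        """Apply a rigid transform ``p -> R p + t`` to the axis."""
        rotation = np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return Axis3D(rotation @ self.point + t, rotation @ self.direction)

    def angle_to(self, other: "Axis3D") -> float:
        """Unsigned angle (degrees) between the two directions, folded to [0, 90]."""
        c = abs(float(np.dot(self.direction, other.direction)))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rot_flexion(angle_deg: float) -> np.ndarray:
    """Rotation about the radioulnar (x) axis tipping distal (+z) palmar (+y).

    ``rot_flexion(theta) @ [0, 0, 1] == [0, sin(theta), cos(theta)]``, so a
    positive angle is flexion under the package's sign convention.
    """
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about an arbitrary axis."""
    k = unit(axis)
    a = np.radians(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(a) * kx + (1 - np.cos(a)) * (kx @ kx)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1.0
    return q


def tls_line_fit(
    points: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through ``points`` (N, d).

    Returns ``(centroid, direction)`` where direction is the first principal
    component of the centered point cloud (orthogonal-distance minimizer).
    Optional nonnegative ``weights`` (e.g. voxel counts behind slice
    centroids) turn this into a weighted orthogonal fit.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("need at least two points for a line fit")
    if weights is None:
        c = points.mean(axis=0)
        centered = points - c
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (points.shape[0],) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        c = (points * w[:, None]).sum(axis=0) / w.sum()
        centered = (points - c) * np.sqrt(w)[:, None]
    # SVD of the centered cloud; right singular vector of the largest value.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12:
        raise ValueError("degenerate point cloud: all points coincide")
    return c, vt[0]


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    a = float(np.mod(angle, 360.0))
    if a > 180.0:
        a -= 360.0
    return a
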