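"""SPC lateral plane, axis projection and the signed radiocarpal angle set.

The lateral viewing plane is operationalized as the plane through the
scaphoid, pisiform and capitate centroids (the scaphopisocapitate alignment
that defines a true lateral wrist view).  Its in-plane basis is ``u`` — the
radius axis direction projected into the plane, distal positive — and ``v``
— dorsopalmar, palmar positive, the sign fixed by requiring the pisiform
centroid to lie palmar.  ``{u, v, normal}`` is right-handed.

Angles are signed with flexion (palmar angulation of the distal bone)
positive, the convention under which a normally flexed scaphoid reads about
+50 degrees and the capitate/metacarpal read slightly negative.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .axes import (
    AxisConfig,
    AxisVariant,
    estimate_centroid_axis,
    estimate_lunate_axial_axis,
    estimate_lunate_tangential_axis,
    estimate_metacarpal_axial_axis,
    estimate_radius_axis,
    estimate_tangential_axis,
)
from .geometry import Axis3D, unit, wrap_angle_deg
from .volume import MEASURED_BONES, BoneLabel, LabeledVolume

__all__ = [
    "LateralPlane",
    "Axis2D",
    "AngleSet",
    "define_spc_lateral_plane",
    "project_axis",
    "signed_angle",
    "compute_angle_set",
    "UnprojectableAxisError",
]

_SPC_BONES = (BoneLabel.SCAPHOID, BoneLabel.PISIFORM, BoneLabel.CAPITATE)

_ANGLE_NAME = {
    BoneLabel.SCAPHOID: "radioscaphoid",
    BoneLabel.LUNATE: "radiolunate",
    BoneLabel.CAPITATE: "radiocapitate",
    BoneLabel.MIDDLE_METACARPAL: "radiometacarpal",
}


class UnprojectableAxisError(ValueError):
    """Axis direction is too close to the plane normal to project."""


@dataclass(frozen=True)
class LateralPlane:
    """Lateral projection plane with an orthonormal right-handed basis.

    ``u`` points distal, ``v`` palmar, ``normal`` radioulnar.
    """

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "u", "v", "normal"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        basis = np.column_stack([self.u, self.v, self.normal])
        if not np.allclose(basis.T @ basis, np.eye(3), atol=1e-8):
            raise ValueError("plane basis {u, v, normal} must be orthonormal")
        if not np.allclose(np.cross(self.u, self.v), self.normal, atol=1e-8):
            raise ValueError("plane basis must be right-handed (u x v = normal)")

    def to_plane_vu(self, points: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points) - self.origin
        return np.column_stack([rel @ self.v, rel @ self.u])


@dataclass(frozen=True)
class Axis2D:
    """In-plane line: point and unit direction, both in (v, u) coordinates."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(2))
        d = np.asarray(self.direction, dtype=float).reshape(2)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("Axis2D direction must be nonzero")
        object.__setattr__(self, "direction", d / n)

    @property
    def angle_deg(self) -> float:
        """Signed angle versus the distal (u) axis, palmar lean positive."""
        return float(np.degrees(np.arctan2(self.direction[0], self.direction[1])))


def define_spc_lateral_plane(
    volume: LabeledVolume,
    cfg: AxisConfig | None = None,
    radius_axis: Axis3D | None = None,
) -> LateralPlane:
    """Lateral plane through the scaphoid, pisiform and capitate centroids.

    The normal sign is chosen so that ``v = normal x u`` points palmar
    (toward the pisiform); ``u`` is the radius axis direction projected into
    the plane.
    """
    for bone in _SPC_BONES:
        volume.require_bone(bone)
    c_s = volume.centroid(BoneLabel.SCAPHOID)
    c_p = volume.centroid(BoneLabel.PISIFORM)
    c_c = volume.centroid(BoneLabel.CAPITATE)
    n = np.cross(c_c - c_s, c_p - c_s)
    scale = max(np.linalg.norm(c_c - c_s), np.linalg.norm(c_p - c_s))
    if np.linalg.norm(n) < 1e-6 * scale**2:
        raise ValueError("scaphoid, pisiform and capitate centroids are collinear")
    n = unit(n)
    if radius_axis is None:
        radius_axis = estimate_radius_axis(volume, cfg)
    d = radius_axis.direction
    u_raw = d - np.dot(d, n) * n
    if np.linalg.norm(u_raw) < 1e-6:
        raise ValueError("radius axis is perpendicular to the SPC plane")
    u = unit(u_raw)
    v = np.cross(n, u)
    origin = (c_s + c_p + c_c) / 3.0
    if float(np.dot(v, c_p - 0.5 * (c_s + c_c))) < 0:
        n, v = -n, -v
    return LateralPlane(origin=origin, u=u, v=v, normal=n)


def project_axis(axis: Axis3D, plane: LateralPlane, min_angle_deg: float = 5.0) -> Axis2D:
    """Orthogonal projection of a 3D axis onto the lateral plane.

    Raises :class:`UnprojectableAxisError` when the axis direction is within
    ``min_angle_deg`` of the plane normal.
    """
    cos_to_normal = abs(float(np.dot(axis.direction, plane.normal)))
    if cos_to_normal > np.cos(np.radians(min_angle_deg)):
        raise UnprojectableAxisError(
            "axis direction is nearly parallel to the lateral-plane normal"
        )
    rel = axis.point - plane.origin
    point_vu = np.array([rel @ plane.v, rel @ plane.u])
    dir_vu = np.array([axis.direction @ plane.v, axis.direction @ plane.u])
    return Axis2D(point_vu, dir_vu)


def signed_angle(radius_axis: Axis2D, bone_axis: Axis2D) -> float:
    """Signed rotation (degrees) from the radius direction to the bone
    direction, flexion (palmar lean of the distal bone) positive, in
    (-180, 180]."""
    return wrap_angle_deg(bone_axis.angle_deg - radius_axis.angle_deg)


@dataclass(frozen=True)
class AngleSet:
    """The four radiocarpal angles, each in axial and tangential variants.

    Angles are degrees, signed flexion-positive, keyed by
    ``(BoneLabel, AxisVariant)``.
    """

    angles: Mapping[tuple[BoneLabel, AxisVariant], float]

    def __post_init__(self) -> None:
        angles = {
            (BoneLabel(int(b)), AxisVariant(v)): float(a)
            for (b, v), a in dict(self.angles).items()
        }
        for bone in MEASURED_BONES:
            for variant in AxisVariant:
                if (bone, variant) not in angles:
                    raise ValueError(f"missing angle for {bone.short}/{variant.value}")
        for key, a in angles.items():
            if not -180.0 < a <= 180.0:
                raise ValueError(f"angle out of range for {key}: {a}")
        object.__setattr__(self, "angles", angles)

    def get(self, bone: BoneLabel, variant: AxisVariant | str = AxisVariant.AXIAL) -> float:
        return self.angles[(BoneLabel(int(bone)), AxisVariant(variant))]

    def to_records(self, wrist_id: str = "wrist000") -> list[dict]:
        """One record per (bone, variant), ready for a long-format table."""
        return [
            {
                "wrist_id": wrist_id,
                "bone": bone.short,
                "angle_name": _ANGLE_NAME[bone],
                "variant": variant.value,
                "angle_deg": round(a, 4),
            }
            for (bone, variant), a in sorted(
                self.angles.items(), key=lambda kv: (int(kv[0][0]), kv[0][1].value)
            )
        ]


def compute_angle_set(volume: LabeledVolume, cfg: AxisConfig | None = None) -> AngleSet:
    """Full measurement pipeline on one volume.

    Estimates the SPC plane and every bone's axial and tangential axis,
    projects them and returns the signed radiocarpal angle set.  Errors from
    component estimators are re-raised annotated with the bone and variant.
    """
    cfg = cfg or AxisConfig()
    radius_axis = estimate_radius_axis(volume, cfg)
    plane = define_spc_lateral_plane(volume, cfg, radius_axis=radius_axis)
    r2 = project_axis(radius_axis, plane)

    def axial(bone: BoneLabel) -> Axis3D:
        if bone == BoneLabel.LUNATE:
            return estimate_lunate_axial_axis(volume)
        if bone == BoneLabel.MIDDLE_METACARPAL:
            return estimate_metacarpal_axial_axis(volume, cfg)
        return estimate_centroid_axis(volume, bone, cfg)

    def tangential(bone: BoneLabel) -> Axis3D:
        if bone == BoneLabel.LUNATE:
            return estimate_lunate_tangential_axis(volume, plane)
        return estimate_tangential_axis(volume, bone, plane)

    angles: dict[tuple[BoneLabel, AxisVariant], float] = {}
    for bone in MEASURED_BONES:
        for variant, estimator in ((AxisVariant.AXIAL, axial), (AxisVariant.TANGENTIAL, tangential)):
            try:
                axis3d = estimator(bone)
                b2 = project_axis(axis3d, plane)
            except ValueError as exc:
                raise type(exc)(f"{bone.short}/{variant.value}: {exc}") from exc
            angles[(bone, variant)] = signed_angle(r2, b2)
    return AngleSet(angles)
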