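"""Labeled voxel volumes of the wrist and their NIfTI round-trip.

A :class:`LabeledVolume` is the geometric substrate of the whole pipeline: a
3D integer grid where each nonzero value is a :class:`BoneLabel`, together
with isotropic spacing, a world origin and an orientation matrix mapping
voxel axes to world axes.

Volumes are written as uncompressed NIfTI (``.nii``) plus a small JSON
sidecar.  NIfTI affines are stored in float32 by the format, so the sidecar
carries the exact float64 spacing/origin/orientation and is preferred on
load; this makes the on-disk round trip bit-exact.
"""
from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "BoneLabel",
    "CARPAL_BONES",
    "MEASURED_BONES",
    "TANGENTIAL_SIDE",
    "LabeledVolume",
    "save_volume",
    "load_volume",
    "MissingBoneError",
]


class MissingBoneError(ValueError):
    """Raised when an operation needs a bone label absent from the volume."""


class BoneLabel(enum.IntEnum):
    """The six bones of the measurement protocol, as voxel label values."""

    RADIUS = 1
    SCAPHOID = 2
    LUNATE = 3
    CAPITATE = 4
    PISIFORM = 5
    MIDDLE_METACARPAL = 6

    @property
    def short(self) -> str:
        return self.name.lower()


#: Carpal bones that may be the target of a stripped reconstruction.
CARPAL_BONES = (
    BoneLabel.SCAPHOID,
    BoneLabel.LUNATE,
    BoneLabel.CAPITATE,
    BoneLabel.PISIFORM,
)

#: Bones whose radiocarpal angle is reported (radius is the reference).
MEASURED_BONES = (
    BoneLabel.SCAPHOID,
    BoneLabel.LUNATE,
    BoneLabel.CAPITATE,
    BoneLabel.MIDDLE_METACARPAL,
)

#: Which silhouette margin defines each bone's tangential axis in the
#: measurement protocol: palmar tangent for the scaphoid, dorsal tangent for
#: capitate and middle metacarpal.  The lunate's tangential axis is the
#: in-plane perpendicular to its distal horn-tip line and is handled
#: separately.
TANGENTIAL_SIDE = {
    BoneLabel.SCAPHOID: "palmar",
    BoneLabel.CAPITATE: "dorsal",
    BoneLabel.MIDDLE_METACARPAL: "dorsal",
}

_VALID_LABELS = frozenset(int(b) for b in BoneLabel)


@dataclass
class LabeledVolume:
    """3D integer-labeled voxel grid with world geometry.

    Parameters
    ----------
    data
        Integer array of shape ``(nx, ny, nz)``; nonzero values must be
        members of :class:`BoneLabel`.
    spacing
        Isotropic voxel edge length in mm (> 0).
    origin
        World coordinates (mm) of the center of voxel ``(0, 0, 0)``.
    orientation
        3x3 orthonormal matrix with determinant +1 mapping voxel axes to
        world axes (identity for canonically generated phantoms).
    """

    data: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be a 3D array")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("volume data must be an integer array")
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if not np.allclose(self.orientation @ self.orientation.T, np.eye(3), atol=1e-9):
            raise ValueError("orientation must be orthonormal")
        if np.linalg.det(self.orientation) < 0:
            raise ValueError("orientation must be proper (determinant +1)")
        labels = set(np.unique(self.data).tolist()) - {0}
        if not labels <= _VALID_LABELS:
            raise ValueError(f"unknown labels present: {sorted(labels - _VALID_LABELS)}")

    # -- queries -----------------------------------------------------------

    def bones_present(self) -> list[BoneLabel]:
        return [BoneLabel(int(v)) for v in np.unique(self.data) if v != 0]

    def has_bone(self, bone: BoneLabel) -> bool:
        return bool(np.any(self.data == int(bone)))

    def require_bone(self, bone: BoneLabel) -> None:
        if not self.has_bone(bone):
            raise MissingBoneError(f"bone {BoneLabel(bone).short!r} is absent from the volume")

    def mask(self, bone: BoneLabel) -> np.ndarray:
        return self.data == int(bone)

    def bone_points(self, bone: BoneLabel) -> np.ndarray:
        """World coordinates (N, 3) of the centers of the bone's voxels."""
        self.require_bone(bone)
        idx = np.argwhere(self.data == int(bone)).astype(float)
        return self.origin + (idx * self.spacing) @ self.orientation.T

    def points_from_indices(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx * self.spacing) @ self.orientation.T

    def centroid(self, bone: BoneLabel) -> np.ndarray:
        return self.bone_points(bone).mean(axis=0)

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = self.orientation * self.spacing
        a[:3, 3] = self.origin
        return a


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".geom.json")
    return path.with_name(name + ".geom.json")


def save_volume(volume: LabeledVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI with an exact-geometry JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.data.astype(np.int16), volume.affine)
    nib.save(img, str(path))
    sidecar = {
        "spacing": volume.spacing,
        "origin": volume.origin.tolist(),
        "orientation": volume.orientation.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def load_volume(path: str | Path) -> LabeledVolume:
    """Read a volume written by :func:`save_volume`.

    The JSON sidecar, when present, supplies the exact float64 geometry;
    otherwise spacing/origin/orientation are recovered from the NIfTI affine.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int16)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return LabeledVolume(
            data,
            spacing=meta["spacing"],
            origin=np.array(meta["origin"]),
            orientation=np.array(meta["orientation"]),
        )
    affine = img.affine
    scales = np.linalg.norm(affine[:3, :3], axis=0)
    spacing = float(scales.mean())
    orientation = affine[:3, :3] / scales
    return LabeledVolume(data, spacing=spacing, origin=affine[:3, 3], orientation=orientation)
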