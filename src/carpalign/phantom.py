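"""Parametric synthetic wrist phantom with analytic ground-truth axes.

The phantom emulates a neutrally positioned wrist imaged for carpal-alignment
measurement: radius, scaphoid, lunate, capitate, pisiform and middle
metacarpal, each a simple solid with an unambiguous analytic long axis, laid
out in the package's world frame (x radioulnar, y dorsopalmar with palmar
positive, z proximodistal with distal positive).

Bone primitives
---------------
* Radius: tapered round cone (hull of two spheres) cut flat at the distal
  articular face, with a label-free medullary canal bored along the shaft.
* Scaphoid, capitate, middle metacarpal: tapered round cones.  The taper is
  chosen per bone so that the palmar (scaphoid) or dorsal (capitate,
  metacarpal) silhouette tangent — the external bitangent of the two end
  circles — makes a configured angle with the long axis.  Because the solids
  are axisymmetric, slice centroids lie exactly on the axis, so the axial
  ground truth is exact while the tangential ground truth differs from it by
  exactly the configured offset.
* Lunate: crescent formed as the difference of two spheres (a concave distal
  articular cup), with two small distal horn spheres unioned at the cup rim
  so the projected silhouette has two identifiable horn tips.
* Pisiform: small ellipsoid (needed only for the scaphopisocapitate lateral
  plane), placed palmar of the capitate.

Each bone is posed by a lateral-plane flexion/extension rotation about its
own center (flexion positive), followed by an optional global rigid
transform of the whole wrist.  Ground-truth axial and tangential axes are
the analytic axes of the primitives after posing; regenerating with the
same pose and seed is bit-identical.

Cohort defaults follow the angle distributions reported for software
measurements of 30 asymptomatic wrists: radioscaphoid 54 (SD 11), radiolunate
0 (13), radiocapitate -13 (7), radiometacarpal -9 (7) degrees, with
tangential-minus-axial offsets of -5, +2, -11 and +7 degrees respectively.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .geometry import Axis3D, rot_flexion, unit
from .volume import TANGENTIAL_SIDE, BoneLabel, LabeledVolume, save_volume

__all__ = [
    "PoseConfig",
    "WristPhantom",
    "generate_phantom",
    "sample_cohort",
    "BoneOverlapError",
    "DEFAULT_SIZES",
    "DEFAULT_ANGLE_MEANS",
    "DEFAULT_ANGLE_SDS",
    "TANGENTIAL_SIDE",
    "tangential_offset",
    "save_phantom",
    "load_phantom",
]


class BoneOverlapError(ValueError):
    """Two posed bone primitives claim the same voxel."""


#: Default anatomical size parameters, mm.  Radii/lengths are of cone-capsule
#: primitives; tangential offsets are the angle (degrees, flexion-positive)
#: between a bone's tangential and axial ground-truth axes.
DEFAULT_SIZES: dict[str, float] = {
    "radius_shaft_length": 58.0,     # distal face to proximal sphere center
    "radius_r_proximal": 6.0,
    "radius_r_distal": 8.5,
    "radius_canal_radius": 2.5,
    "scaphoid_half_length": 8.0,
    "scaphoid_r_proximal": 3.6,
    "scaphoid_tangential_offset": -5.0,
    "capitate_half_length": 8.0,
    "capitate_r_proximal": 2.3,
    "capitate_tangential_offset": -11.0,
    "metacarpal_half_length": 10.0,
    "metacarpal_r_proximal": 5.2,
    "metacarpal_tangential_offset": 7.0,
    "lunate_radius": 7.0,
    "lunate_cup_radius": 9.0,
    "lunate_cup_offset": 8.0,
    "lunate_horn_radius": 2.0,
    "lunate_horn_lift": 0.8,         # horn center height above the cup rim
    "lunate_horn_radial_offset": 1.2,  # horn center outside the rim circle
    "lunate_tangential_offset": 2.0,
    "pisiform_semiaxis_x": 2.8,
    "pisiform_semiaxis_y": 2.5,
    "pisiform_semiaxis_z": 2.2,
}

#: Cohort pose defaults (degrees): software-column means/SDs of the study
#: population (n = 30 asymptomatic wrists).
DEFAULT_ANGLE_MEANS: dict[BoneLabel, float] = {
    BoneLabel.RADIUS: 0.0,
    BoneLabel.SCAPHOID: 54.0,
    BoneLabel.LUNATE: 0.0,
    BoneLabel.CAPITATE: -13.0,
    BoneLabel.PISIFORM: 0.0,
    BoneLabel.MIDDLE_METACARPAL: -9.0,
}
DEFAULT_ANGLE_SDS: dict[BoneLabel, float] = {
    BoneLabel.RADIUS: 0.0,
    BoneLabel.SCAPHOID: 11.0,
    BoneLabel.LUNATE: 13.0,
    BoneLabel.CAPITATE: 7.0,
    BoneLabel.PISIFORM: 0.0,
    BoneLabel.MIDDLE_METACARPAL: 7.0,
}

#: Canonical bone centers (mm) in the neutral wrist.  Scaphoid, pisiform and
#: capitate centers all lie in the x = 0 plane, and every primitive is
#: mirror-symmetric about its own sagittal plane, so per-bone flexion
#: rotations (about x through each bone's center) leave the three SPC
#: centroids exactly in x = 0: the centroid plane is the canonical lateral
#: plane for every pose.  The lunate sits in its own radioulnar lane so its
#: sphere never touches the sagittal bones.
_ANCHORS: dict[BoneLabel, np.ndarray] = {
    BoneLabel.RADIUS: np.array([0.0, 0.0, 0.0]),
    BoneLabel.SCAPHOID: np.array([0.0, 10.0, 14.0]),
    BoneLabel.LUNATE: np.array([13.0, 0.0, 12.0]),
    BoneLabel.CAPITATE: np.array([0.0, -7.0, 24.0]),
    BoneLabel.PISIFORM: np.array([0.0, 21.0, 5.0]),
    BoneLabel.MIDDLE_METACARPAL: np.array([0.0, -1.0, 54.0]),
}

_PAINT_ORDER = (
    BoneLabel.RADIUS,
    BoneLabel.SCAPHOID,
    BoneLabel.LUNATE,
    BoneLabel.CAPITATE,
    BoneLabel.PISIFORM,
    BoneLabel.MIDDLE_METACARPAL,
)


def tangential_offset(bone: BoneLabel, sizes: Mapping[str, float]) -> float:
    """Tangential-minus-axial ground-truth angle (degrees) for ``bone``."""
    if bone == BoneLabel.LUNATE:
        return float(sizes["lunate_tangential_offset"])
    key = {
        BoneLabel.SCAPHOID: "scaphoid_tangential_offset",
        BoneLabel.CAPITATE: "capitate_tangential_offset",
        BoneLabel.MIDDLE_METACARPAL: "metacarpal_tangential_offset",
    }.get(bone)
    if key is None:
        return 0.0
    return float(sizes[key])


def _cone_distal_radius(r_proximal: float, half_length: float, offset_deg: float, side: str) -> float:
    """Distal end-sphere radius realizing a tangential offset on one margin.

    The external bitangent of two circles with radii ``r_p``, ``r_d`` whose
    centers are ``2h`` apart tilts by ``arcsin((r_d - r_p) / (2h))`` toward
    the margin.  On the palmar margin a distally widening bone tips the
    tangent palmar (positive offset); on the dorsal margin the sign flips.
    """
    s = np.sin(np.radians(offset_deg))
    if side == "palmar":
        return r_proximal + 2.0 * half_length * s
    return r_proximal - 2.0 * half_length * s


@dataclass(frozen=True)
class PoseConfig:
    """Per-bone lateral-plane pose plus global rigid transform and sizes.

    ``angles`` maps bones to flexion/extension in degrees (flexion positive);
    missing bones default to 0.  The radius may itself carry an angle, in
    which case ground-truth radiocarpal angles are differences of pose
    angles.  ``global_rotation``/``global_translation`` move the whole wrist
    rigidly after posing.
    """

    angles: Mapping[BoneLabel, float] = field(default_factory=dict)
    global_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    global_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sizes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        angles = {BoneLabel(int(b)): float(a) for b, a in dict(self.angles).items()}
        for bone, a in angles.items():
            if abs(a) > 90.0:
                raise ValueError(f"pose angle for {bone.short} out of range (+-90 deg): {a}")
        merged = dict(DEFAULT_SIZES)
        merged.update({str(k): float(v) for k, v in dict(self.sizes).items()})
        for key, v in merged.items():
            if not key.endswith("_tangential_offset") and v <= 0:
                raise ValueError(f"size parameter {key!r} must be positive, got {v}")
        r = np.asarray(self.global_rotation, dtype=float).reshape(3, 3)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or np.linalg.det(r) < 0:
            raise ValueError("global_rotation must be a proper rotation matrix")
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "sizes", merged)
        object.__setattr__(self, "global_rotation", r)
        object.__setattr__(
            self, "global_translation", np.asarray(self.global_translation, dtype=float).reshape(3)
        )

    def angle(self, bone: BoneLabel) -> float:
        return self.angles.get(bone, 0.0)

    def truth_radiocarpal(self, bone: BoneLabel, variant: str = "axial") -> float:
        """Ground-truth signed radiocarpal angle (degrees) implied by the pose."""
        a = self.angle(bone) - self.angle(BoneLabel.RADIUS)
        if variant == "tangential":
            a += tangential_offset(bone, self.sizes)
        return a

    def with_global(self, rotation: np.ndarray, translation: np.ndarray) -> "PoseConfig":
        return PoseConfig(
            angles=dict(self.angles),
            global_rotation=np.asarray(rotation, float) @ self.global_rotation,
            global_translation=np.asarray(rotation, float) @ self.global_translation
            + np.asarray(translation, float),
            sizes=dict(self.sizes),
        )

    def to_jsonable(self) -> dict:
        return {
            "angles": {BoneLabel(b).short: a for b, a in self.angles.items()},
            "global_rotation": self.global_rotation.tolist(),
            "global_translation": self.global_translation.tolist(),
            "sizes": dict(self.sizes),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "PoseConfig":
        angles = {BoneLabel[b.upper()]: a for b, a in d.get("angles", {}).items()}
        return cls(
            angles=angles,
            global_rotation=np.array(d.get("global_rotation", np.eye(3).tolist())),
            global_translation=np.array(d.get("global_translation", [0.0, 0.0, 0.0])),
            sizes=d.get("sizes", {}),
        )


# ---------------------------------------------------------------------------
# Implicit solids
# ---------------------------------------------------------------------------


def _sd_round_cone(p: np.ndarray, r1: float, r2: float, length: float) -> np.ndarray:
    """Signed distance to the hull of spheres (0,0,0,r1) and (0,0,L,r2).

    ``p`` is (N, 3) in the cone's local frame with the axis along +z from the
    proximal sphere center at the origin.
    """
    t = p[:, 2]
    q = np.hypot(p[:, 0], p[:, 1])
    b = (r1 - r2) / length
    a = np.sqrt(max(1.0 - b * b, 0.0))
    k = q * (-b) + t * a
    d_body = q * a + t * b - r1
    d1 = np.hypot(q, t) - r1
    d2 = np.hypot(q, t - length) - r2
    return np.where(k < 0.0, d1, np.where(k > a * length, d2, d_body))


class _Bone:
    """A posed bone primitive: inside test, bounds and truth axes."""

    def __init__(self, label: BoneLabel, pose: PoseConfig):
        self.label = label
        self.pose = pose
        s = pose.sizes
        self.center = _ANCHORS[label].copy()
        self.rot = rot_flexion(pose.angle(label))  # local -> pre-global world
        self.grot = pose.global_rotation
        self.gtrans = pose.global_translation
        self._build(s)

    # -- frames ------------------------------------------------------------

    def world_center(self) -> np.ndarray:
        return self.grot @ self.center + self.gtrans

    def to_local(self, p: np.ndarray) -> np.ndarray:
        """Map (N, 3) world points into the bone's local frame."""
        q = (p - self.gtrans) @ self.grot  # rows @ R == R.T applied per point
        return (q - self.center) @ self.rot

    def local_dir_to_world(self, d: np.ndarray) -> np.ndarray:
        return self.grot @ (self.rot @ np.asarray(d, float))

    def local_pt_to_world(self, p: np.ndarray) -> np.ndarray:
        return self.grot @ (self.rot @ np.asarray(p, float) + self.center) + self.gtrans

    # -- per-shape setup ---------------------------------------------------

    def _build(self, s: Mapping[str, float]) -> None:
        lbl = self.label
        if lbl == BoneLabel.RADIUS:
            self.kind = "radius"
            self.L = float(s["radius_shaft_length"])
            self.r1 = float(s["radius_r_proximal"])
            self.r2 = float(s["radius_r_distal"])
            self.canal_r = float(s["radius_canal_radius"])
            # local frame: distal articular face at z = 0, shaft toward -z
            self._spheres = [(np.array([0.0, 0.0, -self.L]), self.r1), (np.zeros(3), self.r2)]
        elif lbl in TANGENTIAL_SIDE:
            self.kind = "cone"
            prefix = {
                BoneLabel.SCAPHOID: "scaphoid",
                BoneLabel.CAPITATE: "capitate",
                BoneLabel.MIDDLE_METACARPAL: "metacarpal",
            }[lbl]
            self.h = float(s[f"{prefix}_half_length"])
            self.r1 = float(s[f"{prefix}_r_proximal"])
            off = float(s[f"{prefix}_tangential_offset"])
            self.r2 = _cone_distal_radius(self.r1, self.h, off, TANGENTIAL_SIDE[lbl])
            if self.r2 <= 0:
                raise ValueError(f"{prefix} tangential offset too large for its radius")
            self.offset = off
            # the metacarpal's proximal (carpometacarpal) base is cut flat,
            # as in the real bone; scaphoid/capitate keep rounded poles
            self.flat_proximal = lbl == BoneLabel.MIDDLE_METACARPAL
            self._spheres = [
                (np.array([0.0, 0.0, -self.h]), self.r1),
                (np.array([0.0, 0.0, self.h]), self.r2),
            ]
        elif lbl == BoneLabel.LUNATE:
            self.kind = "lunate"
            self.R = float(s["lunate_radius"])
            self.Rc = float(s["lunate_cup_radius"])
            self.dc = float(s["lunate_cup_offset"])
            self.rh = float(s["lunate_horn_radius"])
            lift = float(s["lunate_horn_lift"])
            radial = float(s["lunate_horn_radial_offset"])
            self.offset = float(s["lunate_tangential_offset"])
            # rim circle of the cup (intersection of the two spheres); horn
            # centers sit just outside it so the horns do not bite into the
            # concave articular surface
            z_rim = (self.R**2 - self.Rc**2 + self.dc**2) / (2.0 * self.dc)
            r_rim = float(np.sqrt(self.R**2 - z_rim**2))
            self.z_rim, self.r_rim = z_rim, r_rim
            tilt = rot_flexion(self.offset)
            self.horns = [
                tilt @ np.array([0.0, +(r_rim + radial), z_rim + lift]),
                tilt @ np.array([0.0, -(r_rim + radial), z_rim + lift]),
            ]
            self._spheres = [(np.zeros(3), self.R)] + [(h, self.rh) for h in self.horns]
        elif lbl == BoneLabel.PISIFORM:
            self.kind = "ellipsoid"
            self.semi = np.array(
                [s["pisiform_semiaxis_x"], s["pisiform_semiaxis_y"], s["pisiform_semiaxis_z"]]
            )
            self._spheres = [(np.zeros(3), float(self.semi.max()))]
        else:  # pragma: no cover - enum is exhaustive
            raise ValueError(f"no primitive for {lbl}")

    # -- geometry ----------------------------------------------------------

    def bounding_spheres_world(self) -> list[tuple[np.ndarray, float]]:
        return [(self.local_pt_to_world(c), r) for c, r in self._spheres]

    def inside(self, p_world: np.ndarray) -> np.ndarray:
        """Boolean inside test for (N, 3) world points."""
        q = ((p_world - self.gtrans) @ self.grot - self.center) @ self.rot
        if self.kind == "radius":
            shifted = q + np.array([0.0, 0.0, self.L])
            body = (_sd_round_cone(shifted, self.r1, self.r2, self.L) <= 0.0) & (q[:, 2] <= 0.0)
            rad = np.hypot(q[:, 0], q[:, 1])
            canal = (rad <= self.canal_r) & (q[:, 2] >= -self.L + 4.0) & (q[:, 2] <= -8.0)
            return body & ~canal
        if self.kind == "cone":
            shifted = q + np.array([0.0, 0.0, self.h])
            out = _sd_round_cone(shifted, self.r1, self.r2, 2.0 * self.h) <= 0.0
            if self.flat_proximal:
                out &= q[:, 2] >= -self.h
            return out
        if self.kind == "lunate":
            d0 = np.linalg.norm(q, axis=1)
            dcup = np.linalg.norm(q - np.array([0.0, 0.0, self.dc]), axis=1)
            body = (d0 <= self.R) & (dcup >= self.Rc)
            out = body
            for hc in self.horns:
                out = out | (np.linalg.norm(q - hc, axis=1) <= self.rh)
            return out
        if self.kind == "ellipsoid":
            return np.sum((q / self.semi) ** 2, axis=1) <= 1.0
        raise AssertionError(self.kind)

    # -- ground truth ------------------------------------------------------

    def truth_axes(self) -> dict[str, Axis3D]:
        z = np.array([0.0, 0.0, 1.0])
        axial_dir = self.local_dir_to_world(z)
        point = self.world_center()
        if self.kind == "radius":
            # axis anchored mid-segment of the shaft
            point = self.local_pt_to_world(np.array([0.0, 0.0, -self.L / 2.0]))
            return {"axial": Axis3D(point, axial_dir), "tangential": Axis3D(point, axial_dir)}
        if self.kind == "cone":
            tang_dir = self.local_dir_to_world(rot_flexion(self.offset) @ z)
            side_y = {"palmar": 1.0, "dorsal": -1.0}[TANGENTIAL_SIDE[self.label]]
            r_mid = 0.5 * (self.r1 + self.r2)
            tang_pt = self.local_pt_to_world(np.array([0.0, side_y * r_mid, 0.0]))
            return {"axial": Axis3D(point, axial_dir), "tangential": Axis3D(tang_pt, tang_dir)}
        if self.kind == "lunate":
            tang_dir = self.local_dir_to_world(rot_flexion(self.offset) @ z)
            mid = 0.5 * (self.horns[0] + self.horns[1])
            return {
                "axial": Axis3D(point, axial_dir),
                "tangential": Axis3D(self.local_pt_to_world(mid), tang_dir),
            }
        return {"axial": Axis3D(point, axial_dir), "tangential": Axis3D(point, axial_dir)}


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


@dataclass
class WristPhantom:
    """A labeled wrist volume plus analytic ground truth.

    The voxel volume is generated lazily on first access of :attr:`volume`;
    ground-truth axes and pose-implied angles never require voxelization.
    """

    pose: PoseConfig
    spacing: float
    seed: int
    wrist_id: str = "wrist000"
    truth_axes: dict[BoneLabel, dict[str, Axis3D]] = field(default_factory=dict)
    _volume: LabeledVolume | None = field(default=None, repr=False)

    @property
    def volume(self) -> LabeledVolume:
        if self._volume is None:
            self._volume = _voxelize(self.pose, self.spacing)
        return self._volume

    def truth_angle(self, bone: BoneLabel, variant: str = "axial") -> float:
        return self.pose.truth_radiocarpal(bone, variant)


def _bones(pose: PoseConfig) -> list[_Bone]:
    return [_Bone(lbl, pose) for lbl in _PAINT_ORDER]


def _voxelize(pose: PoseConfig, spacing: float, margin: float = 2.0) -> LabeledVolume:
    bones = _bones(pose)
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for b in bones:
        for c, r in b.bounding_spheres_world():
            lo = np.minimum(lo, c - r)
            hi = np.maximum(hi, c + r)
    lo -= margin
    hi += margin
    origin = np.floor(lo / spacing) * spacing
    shape = np.ceil((hi - origin) / spacing).astype(int) + 1
    data = np.zeros(tuple(shape), dtype=np.int16)
    axes_coords = [origin[k] + spacing * np.arange(shape[k]) for k in range(3)]

    for b in bones:
        blo = np.full(3, np.inf)
        bhi = np.full(3, -np.inf)
        for c, r in b.bounding_spheres_world():
            blo = np.minimum(blo, c - r - spacing)
            bhi = np.maximum(bhi, c + r + spacing)
        i0 = np.maximum(np.floor((blo - origin) / spacing).astype(int), 0)
        i1 = np.minimum(np.ceil((bhi - origin) / spacing).astype(int) + 1, shape)
        if np.any(i0 >= i1):
            continue
        xs = axes_coords[0][i0[0] : i1[0]]
        ys = axes_coords[1][i0[1] : i1[1]]
        zs = axes_coords[2][i0[2] : i1[2]]
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        inside = b.inside(pts).reshape(gx.shape)
        sub = data[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]]
        clash = inside & (sub != 0)
        if np.any(clash):
            other = BoneLabel(int(sub[clash][0]))
            raise BoneOverlapError(
                f"posed primitives overlap: {other.short} and {b.label.short}"
            )
        sub[inside] = int(b.label)
    return LabeledVolume(data, spacing=spacing, origin=origin)


def generate_phantom(
    pose: PoseConfig | None = None,
    spacing: float = 0.4,
    seed: int = 0,
    wrist_id: str = "wrist000",
) -> WristPhantom:
    """Build a wrist phantom with analytic ground-truth axes.

    ``spacing`` must lie in [0.2, 1.0] mm (cone-beam CT order).  The voxel
    volume is computed lazily; overlapping primitives raise
    :class:`BoneOverlapError` naming the colliding pair at voxelization time.
    """
    pose = pose if pose is not None else PoseConfig()
    if not 0.2 <= spacing <= 1.0:
        raise ValueError(f"spacing must be in [0.2, 1.0] mm, got {spacing}")
    truth = {b.label: b.truth_axes() for b in _bones(pose)}
    return WristPhantom(pose=pose, spacing=spacing, seed=int(seed), wrist_id=wrist_id, truth_axes=truth)


def sample_cohort(
    n: int,
    angle_means: Mapping[BoneLabel, float] | None = None,
    angle_sds: Mapping[BoneLabel, float] | None = None,
    seed: int = 0,
    spacing: float = 0.4,
    sizes: Mapping[str, float] | None = None,
) -> list[WristPhantom]:
    """Draw ``n`` phantoms with per-bone pose angles ~ Normal(mean, sd).

    Angles are drawn independently per bone and wrist; per-wrist seeds are
    derived deterministically from the master ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    means = dict(DEFAULT_ANGLE_MEANS)
    if angle_means:
        means.update({BoneLabel(int(b)): float(v) for b, v in angle_means.items()})
    sds = dict(DEFAULT_ANGLE_SDS)
    if angle_sds:
        sds.update({BoneLabel(int(b)): float(v) for b, v in angle_sds.items()})
    if any(v < 0 for v in sds.values()):
        raise ValueError("angle SDs must be nonnegative")
    ss = np.random.SeedSequence(int(seed))
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    rng = np.random.default_rng(ss.spawn(1)[0])
    cohort: list[WristPhantom] = []
    for i in range(n):
        angles = {b: rng.normal(means[b], sds[b]) if sds[b] > 0 else means[b] for b in means}
        # keep draws inside the pose validity range; at the default SDs this
        # clip is ~4 sigma out and essentially never binds
        angles = {b: float(np.clip(a, -89.0, 89.0)) for b, a in angles.items()}
        pose = PoseConfig(angles=angles, sizes=dict(sizes) if sizes else {})
        cohort.append(
            generate_phantom(pose, spacing=spacing, seed=child_seeds[i], wrist_id=f"wrist{i:03d}")
        )
    return cohort


# ---------------------------------------------------------------------------
# Disk round trip (NIfTI + JSON sidecar with pose, truth axes and seed)
# ---------------------------------------------------------------------------


def _axis_jsonable(a: Axis3D) -> dict:
    return {"point": a.point.tolist(), "direction": a.direction.tolist()}


def save_phantom(phantom: WristPhantom, directory: str | Path) -> Path:
    """Write volume (NIfTI) plus a JSON sidecar with pose/truth/seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vol_path = directory / f"{phantom.wrist_id}.nii"
    save_volume(phantom.volume, vol_path)
    meta = {
        "wrist_id": phantom.wrist_id,
        "seed": phantom.seed,
        "spacing": phantom.spacing,
        "pose": phantom.pose.to_jsonable(),
        "truth_axes": {
            bone.short: {v: _axis_jsonable(ax) for v, ax in axes.items()}
            for bone, axes in phantom.truth_axes.items()
        },
    }
    (directory / f"{phantom.wrist_id}.phantom.json").write_text(json.dumps(meta, indent=1))
    return vol_path


def load_phantom(directory: str | Path, wrist_id: str) -> WristPhantom:
    from .volume import load_volume

    directory = Path(directory)
    meta = json.loads((directory / f"{wrist_id}.phantom.json").read_text())
    pose = PoseConfig.from_jsonable(meta["pose"])
    phantom = generate_phantom(pose, spacing=meta["spacing"], seed=meta["seed"], wrist_id=wrist_id)
    vol_path = directory / f"{wrist_id}.nii"
    if vol_path.exists():
        phantom._volume = load_volume(vol_path)
    return phantom
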