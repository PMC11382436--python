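"""Digitally reconstructed radiographs: summation images, bone stripping,
and pseudorandom rotation bookkeeping.

A summation image integrates material path length (mm) along rays parallel
to the lateral-plane normal, mimicking a lateral radiograph reconstructed
from CT data.  Stripped images keep only the bone under assessment plus the
radius and middle metacarpal as a frame of reference, removing landmark
overlap.  Uniform path-length weighting is the declared model — no
attenuation physics.

Image layout: ``pixels[row, col]`` with rows advancing distally along the
plane's ``u`` axis and columns advancing palmarly along ``v``.  "Vertical"
in the annotation sense is the row axis, so an image rendered from a
volume whose radius axis defines ``u`` shows the radius vertical; the study
protocol then rotates each wrist's images by a pseudorandom 1-10 degrees,
the same rotation for every image of that wrist.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .projection import LateralPlane
from .volume import CARPAL_BONES, BoneLabel, LabeledVolume

__all__ = [
    "DRRImage",
    "RotationLog",
    "render_summation",
    "render_stripped",
    "assign_rotations",
    "rotate_in_plane",
    "radius_axis_error",
    "estimate_dominant_axis_angle",
    "save_image",
    "load_image",
]


@dataclass(frozen=True)
class DRRImage:
    """A rendered 2D summation image.

    ``pixels`` are summed material path lengths in mm (non-negative);
    ``origin_vu`` is the (v, u) plane coordinate of pixel (row 0, col 0)'s
    center; ``applied_rotation`` accumulates in-plane rotations applied
    after rendering, degrees in [0, 360).
    """

    pixels: np.ndarray
    pixel_spacing: float
    included_bones: frozenset[BoneLabel]
    applied_rotation: float = 0.0
    wrist_id: str = "wrist000"
    origin_vu: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=float))
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if np.any(self.pixels < -1e-9):
            raise ValueError("pixel intensities must be non-negative")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        included = frozenset(BoneLabel(int(b)) for b in self.included_bones)
        if not included:
            raise ValueError("included_bones must be non-empty")
        object.__setattr__(self, "included_bones", included)
        object.__setattr__(self, "applied_rotation", float(self.applied_rotation) % 360.0)


@dataclass(frozen=True)
class RotationLog:
    """Per-wrist pseudorandom rotation, one value per wrist.

    The protocol applies the same rotation to every reconstructed image of
    a given wrist, so a single number per wrist suffices.
    """

    rotations: dict[str, float]
    seed: int

    def rotation_for(self, wrist_id: str) -> float:
        if wrist_id not in self.rotations:
            raise KeyError(f"wrist {wrist_id!r} not present in the rotation log")
        return self.rotations[wrist_id]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"seed": self.seed, "rotations": self.rotations}, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RotationLog":
        d = json.loads(Path(path).read_text())
        return cls(rotations={k: float(v) for k, v in d["rotations"].items()}, seed=int(d["seed"]))


def render_summation(
    volume: LabeledVolume,
    plane: LateralPlane,
    included: set[BoneLabel] | None = None,
    pixel_spacing: float = 0.4,
    wrist_id: str = "wrist000",
    margin: float = 2.0,
    like: DRRImage | None = None,
) -> DRRImage:
    """Render a parallel-ray summation image of the selected bones.

    Each voxel deposits its material volume into the pixel containing its
    projected center, so a pixel's value approximates the summed path
    length (mm) along the ray through it; the rendering is exactly linear
    in the included bone set.  Pass ``like`` to reuse another image's pixel
    grid (origin and shape), making per-bone renders directly addable.
    """
    present = set(volume.bones_present())
    if included is None:
        included = present
    included = {BoneLabel(int(b)) for b in included}
    if not included:
        raise ValueError("included bone set must not be empty")
    missing = included - present
    if missing:
        raise ValueError(f"bones not present in volume: {[b.short for b in missing]}")

    sel = np.isin(volume.data, [int(b) for b in included])
    idx = np.argwhere(sel)
    pts = volume.points_from_indices(idx)
    rel = pts - plane.origin
    v = rel @ plane.v
    u = rel @ plane.u
    if like is not None:
        if like.pixel_spacing != pixel_spacing:
            raise ValueError("grid reuse requires matching pixel spacing")
        v0, u0 = like.origin_vu
        n_rows, n_cols = like.pixels.shape
    else:
        v0 = v.min() - margin
        u0 = u.min() - margin
        n_cols = int(np.ceil((v.max() + margin - v0) / pixel_spacing)) + 1
        n_rows = int(np.ceil((u.max() + margin - u0) / pixel_spacing)) + 1
    cols = np.floor((v - v0) / pixel_spacing + 0.5).astype(int)
    rows = np.floor((u - u0) / pixel_spacing + 0.5).astype(int)
    if np.any((cols < 0) | (cols >= n_cols) | (rows < 0) | (rows >= n_rows)):
        raise ValueError("reused grid does not cover the included bones")
    img = np.zeros((n_rows, n_cols))
    # each voxel carries volume spacing^3 spread over a pixel area
    np.add.at(img, (rows, cols), volume.spacing**3 / pixel_spacing**2)
    return DRRImage(
        pixels=img,
        pixel_spacing=pixel_spacing,
        included_bones=frozenset(included),
        wrist_id=wrist_id,
        origin_vu=(float(v0), float(u0)),
    )


def render_stripped(
    volume: LabeledVolume,
    plane: LateralPlane,
    target: BoneLabel,
    pixel_spacing: float = 0.4,
    wrist_id: str = "wrist000",
) -> DRRImage:
    """Render the assessment image for one carpal bone: the target plus the
    radius and middle metacarpal as a frame of reference, all other bones
    digitally removed."""
    target = BoneLabel(int(target))
    if target not in CARPAL_BONES:
        raise ValueError(f"{target.short} is not a strippable carpal target")
    volume.require_bone(target)
    included = {target, BoneLabel.RADIUS, BoneLabel.MIDDLE_METACARPAL}
    included &= set(volume.bones_present()) | {target}
    return render_summation(
        volume, plane, included, pixel_spacing=pixel_spacing, wrist_id=wrist_id
    )


def assign_rotations(
    wrist_ids: list[str], lo: float = 1.0, hi: float = 10.0, seed: int = 0
) -> RotationLog:
    """Draw one uniform rotation in [lo, hi] degrees per wrist.

    Deterministic for a given seed; each wrist's rotation is reused for all
    of its reconstructed images.
    """
    if not 0 <= lo < hi:
        raise ValueError("need 0 <= lo < hi for the rotation range")
    if len(set(wrist_ids)) != len(wrist_ids):
        raise ValueError("duplicate wrist ids in rotation assignment")
    rng = np.random.default_rng(seed)
    rotations = {wid: float(rng.uniform(lo, hi)) for wid in wrist_ids}
    return RotationLog(rotations=rotations, seed=int(seed))


def rotate_in_plane(image: DRRImage, theta: float) -> DRRImage:
    """Rotate the image content by ``theta`` degrees about its center.

    A positive ``theta`` tips a previously vertical structure palmar at its
    distal end, i.e. a structure's angle-versus-vertical increases by
    ``theta``.  Resampling is bilinear; ``applied_rotation`` accumulates.
    """
    if abs(theta) >= 90.0:
        raise ValueError("in-plane rotation must satisfy |theta| < 90 degrees")
    # pad the canvas so no content is clipped by the rotation
    h, w = image.pixels.shape
    diag = int(np.ceil(np.hypot(h, w)))
    pad_r = max((diag - h) // 2 + 1, 0)
    pad_c = max((diag - w) // 2 + 1, 0)
    padded = np.pad(image.pixels, ((pad_r, pad_r), (pad_c, pad_c)))
    rotated = ndimage.rotate(padded, theta, reshape=False, order=1, prefilter=False)
    rotated = np.clip(rotated, 0.0, None)
    origin = (
        image.origin_vu[0] - pad_c * image.pixel_spacing,
        image.origin_vu[1] - pad_r * image.pixel_spacing,
    )
    return replace(
        image,
        pixels=rotated,
        applied_rotation=image.applied_rotation + theta,
        origin_vu=origin,
    )


def radius_axis_error(
    drawn_angle_vs_vertical: float, log: RotationLog, wrist_id: str
) -> float:
    """Signed error of a drawn radius axis: drawn angle minus the known
    applied rotation for that wrist."""
    return float(drawn_angle_vs_vertical) - log.rotation_for(wrist_id)


def estimate_dominant_axis_angle(image: DRRImage) -> float:
    """Angle versus vertical (degrees, palmar lean positive) of the image's
    dominant elongated structure, from intensity-weighted second moments.

    Intended for single-bone renders (e.g. a radius-only image) where the
    principal axis of the intensity distribution is the bone axis.
    """
    img = image.pixels
    total = img.sum()
    if total <= 0:
        raise ValueError("cannot estimate an axis on an empty image")
    rows, cols = np.indices(img.shape)
    w = img / total
    r0 = (rows * w).sum()
    c0 = (cols * w).sum()
    dr = rows - r0
    dc = cols - c0
    cov = np.array(
        [
            [(dr * dr * w).sum(), (dr * dc * w).sum()],
            [(dr * dc * w).sum(), (dc * dc * w).sum()],
        ]
    )
    evals, evecs = np.linalg.eigh(cov)
    principal = evecs[:, int(np.argmax(evals))]  # (d_row, d_col)
    # rows advance distally, cols palmarly: angle vs vertical (row axis)
    ang = float(np.degrees(np.arctan2(principal[1], principal[0])))
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return ang


# ---------------------------------------------------------------------------
# Disk I/O: 16-bit PNG plus JSON sidecar
# ---------------------------------------------------------------------------

_INTENSITY_SCALE = 100.0  # stored counts per mm of path length


def save_image(image: DRRImage, path: str | Path) -> Path:
    """Write as 16-bit PNG (fixed 0.01 mm intensity quantization) with a
    JSON sidecar carrying geometry and bookkeeping."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    counts = np.round(image.pixels * _INTENSITY_SCALE)
    if counts.max() > 65535:
        raise ValueError("path length exceeds the 16-bit intensity range")
    iio.imwrite(path, counts.astype(np.uint16))
    sidecar = {
        "wrist_id": image.wrist_id,
        "included_bones": sorted(b.short for b in image.included_bones),
        "applied_rotation": image.applied_rotation,
        "pixel_spacing": image.pixel_spacing,
        "origin_vu": list(image.origin_vu),
        "intensity_scale": _INTENSITY_SCALE,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_image(path: str | Path) -> DRRImage:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    counts = iio.imread(path).astype(float)
    return DRRImage(
        pixels=counts / meta["intensity_scale"],
        pixel_spacing=meta["pixel_spacing"],
        included_bones=frozenset(BoneLabel[b.upper()] for b in meta["included_bones"]),
        applied_rotation=meta["applied_rotation"],
        wrist_id=meta["wrist_id"],
        origin_vu=tuple(meta["origin_vu"]),
    )
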