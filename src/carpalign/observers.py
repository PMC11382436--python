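"""Simulated manual measurement of reconstructed radiographs.

The study's manual arm has hand surgeons draw bone axes on lateral
reconstructions; the drawn lines are reduced to angles versus the image
vertical, and radiocarpal angles are differences of those per-wrist
readings.  This module models that process: annotation lines to angles,
angle composition, and a configurable simulated observer pool.

Observer error is modeled as additive Gaussian noise on the measured angle
(plus an optional systematic bias), not as endpoint noise — the downstream
reliability statistics consume angles only.  Two observer groups are
distinguished: *uninstructed* observers annotate only the summation images
using whichever axis variant they prefer (all but one prefer the axial
axes); *instructed* observers draw both axis variants on both the summation
and stripped image sets.  Each observer measures every wrist twice, in two
sessions with independently shuffled wrist order and independent error
draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .axes import AxisVariant
from .drr import RotationLog
from .phantom import WristPhantom
from .volume import MEASURED_BONES, BoneLabel

__all__ = [
    "AnnotationLine",
    "ObserverProfile",
    "MeasurementTable",
    "annotation_to_angle",
    "radiocarpal_from_annotations",
    "simulate_session",
    "make_observer_pool",
    "IMAGE_KINDS",
]

IMAGE_KINDS = ("summation", "stripped")

#: Default angular noise SDs (degrees) per image kind.  Chosen so the
#: simulated observer pools land in realistic reliability territory: the
#: stripped images, free of bone overlap, are read far more consistently
#: than the summation images, and the radius axis — a long unambiguous
#: shaft — is read most consistently of all.  This is a calibration of the
#: simulator, not an estimate from data.
DEFAULT_NOISE_SD = {
    "summation": {
        BoneLabel.RADIUS: 0.8,
        BoneLabel.SCAPHOID: 4.0,
        BoneLabel.LUNATE: 3.5,
        BoneLabel.CAPITATE: 3.0,
        BoneLabel.MIDDLE_METACARPAL: 2.0,
    },
    "stripped": {
        BoneLabel.RADIUS: 0.6,
        BoneLabel.SCAPHOID: 1.6,
        BoneLabel.LUNATE: 1.6,
        BoneLabel.CAPITATE: 1.4,
        BoneLabel.MIDDLE_METACARPAL: 1.0,
    },
}


@dataclass(frozen=True)
class AnnotationLine:
    """A drawn axis: two endpoints in image (column, row) pixel coordinates."""

    endpoints: tuple[tuple[float, float], tuple[float, float]]
    bone: BoneLabel
    variant: AxisVariant = AxisVariant.AXIAL
    observer_id: str = "obs00"
    session: int = 1
    wrist_id: str = "wrist000"

    def __post_init__(self) -> None:
        (x1, y1), (x2, y2) = self.endpoints
        if abs(x1 - x2) < 1e-12 and abs(y1 - y2) < 1e-12:
            raise ValueError("annotation endpoints must be distinct")
        if self.session not in (1, 2):
            raise ValueError("session must be 1 or 2")


def annotation_to_angle(line: AnnotationLine) -> float:
    """Signed angle (degrees) between the drawn line and the image vertical.

    Images place rows distal-ascending and columns palmar-ascending, so a
    line leaning palmar at its distal end reads positive.  The result lies
    in (-90, 90] and is independent of endpoint order.
    """
    (x1, y1), (x2, y2) = line.endpoints
    ang = float(np.degrees(np.arctan2(x2 - x1, y2 - y1)))
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return ang


def radiocarpal_from_annotations(bone_angle: float, radius_angle: float) -> float:
    """Compose per-line angle-versus-vertical readings into a radiocarpal
    angle (flexion positive): bone minus radius."""
    return float(bone_angle) - float(radius_angle)


@dataclass(frozen=True)
class ObserverProfile:
    """One simulated observer.

    ``noise_sd`` maps image kind -> bone -> angular SD in degrees;
    ``bias`` maps bone -> systematic offset (defaults to zero — the study
    gives no per-observer bias estimates, so it is exposed as a knob).
    ``preferred_variant`` applies to uninstructed observers, who draw one
    axis per bone on summation images only.
    """

    observer_id: str
    instructed: bool
    noise_sd: Mapping[str, Mapping[BoneLabel, float]] = field(
        default_factory=lambda: DEFAULT_NOISE_SD
    )
    bias: Mapping[BoneLabel, float] = field(default_factory=dict)
    preferred_variant: Mapping[BoneLabel, AxisVariant] = field(default_factory=dict)
    experience_years: float = 10.0
    seed: int = 0
    requested_kinds: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for kind, per_bone in self.noise_sd.items():
            if kind not in IMAGE_KINDS:
                raise ValueError(f"unknown image kind {kind!r}")
            for bone, sd in per_bone.items():
                if sd < 0:
                    raise ValueError(f"noise SD must be >= 0 ({kind}/{BoneLabel(bone).short})")
        if self.requested_kinds is not None:
            unknown = set(self.requested_kinds) - set(IMAGE_KINDS)
            if unknown:
                raise ValueError(f"unknown image kinds requested: {sorted(unknown)}")
            if not self.instructed and "stripped" in self.requested_kinds:
                raise ValueError("uninstructed observers annotate only summation images")

    def image_kinds(self) -> tuple[str, ...]:
        if self.requested_kinds is not None:
            return tuple(self.requested_kinds)
        return IMAGE_KINDS if self.instructed else ("summation",)

    def variants_for(self, bone: BoneLabel) -> tuple[AxisVariant, ...]:
        if bone == BoneLabel.RADIUS:
            return (AxisVariant.AXIAL,)
        if self.instructed:
            return (AxisVariant.AXIAL, AxisVariant.TANGENTIAL)
        return (self.preferred_variant.get(bone, AxisVariant.AXIAL),)


def make_observer_pool(
    n_uninstructed: int = 7,
    n_instructed: int = 6,
    seed: int = 0,
    noise_sd: Mapping[str, Mapping[BoneLabel, float]] | None = None,
) -> list[ObserverProfile]:
    """Build the study-shaped observer pool.

    Seven uninstructed observers (mean experience 17 years) annotate only
    summation images; all prefer the axial axes except one, who draws
    tangential axes for the scaphoid and lunate.  Six instructed observers
    (mean experience 8 years) annotate both image sets with both variants.
    """
    rng = np.random.default_rng(seed)
    noise = noise_sd or DEFAULT_NOISE_SD
    pool: list[ObserverProfile] = []
    for i in range(n_uninstructed):
        preferred = {}
        if i == n_uninstructed - 1 and n_uninstructed > 1:
            preferred = {
                BoneLabel.SCAPHOID: AxisVariant.TANGENTIAL,
                BoneLabel.LUNATE: AxisVariant.TANGENTIAL,
            }
        pool.append(
            ObserverProfile(
                observer_id=f"uninstructed{i:02d}",
                instructed=False,
                noise_sd=noise,
                preferred_variant=preferred,
                experience_years=float(np.clip(rng.normal(17.0, 11.0), 3.0, 45.0)),
                seed=int(rng.integers(2**31)),
            )
        )
    for i in range(n_instructed):
        pool.append(
            ObserverProfile(
                observer_id=f"instructed{i:02d}",
                instructed=True,
                noise_sd=noise,
                experience_years=float(np.clip(rng.normal(8.0, 5.0), 2.0, 40.0)),
                seed=int(rng.integers(2**31)),
            )
        )
    return pool


_COLUMNS = [
    "wrist_id",
    "observer_id",
    "instructed",
    "session",
    "bone",
    "variant",
    "image_kind",
    "angle_deg",
]


@dataclass
class MeasurementTable:
    """Long-format angle-versus-vertical measurements.

    One row per (wrist, observer, session, bone, variant, image kind); the
    ``angle_deg`` column is the drawn axis angle versus the image vertical,
    radius rows included so radiocarpal angles can be composed downstream.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        self.df = self.df[_COLUMNS].reset_index(drop=True)
        key = ["wrist_id", "observer_id", "session", "bone", "variant", "image_kind"]
        if self.df.duplicated(subset=key).any():
            raise ValueError("duplicate measurement keys in table")
        if not np.all(np.isfinite(self.df["angle_deg"])):
            raise ValueError("non-finite angles in measurement table")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        out = self.df.copy()
        out["angle_deg"] = out["angle_deg"].map(lambda a: f"{a:.4f}")
        out.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementTable":
        df = pd.read_csv(path, dtype={"session": int})
        df["instructed"] = df["instructed"].astype(bool)
        df["angle_deg"] = df["angle_deg"].astype(float)
        return cls(df)

    @classmethod
    def concat(cls, tables: Iterable["MeasurementTable"]) -> "MeasurementTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))

    def radiocarpal(self) -> pd.DataFrame:
        """Per-row radiocarpal angles: each bone reading minus the matching
        radius reading of the same wrist/observer/session/image kind."""
        df = self.df
        radius = df[df["bone"] == BoneLabel.RADIUS.short]
        key = ["wrist_id", "observer_id", "session", "image_kind"]
        merged = df[df["bone"] != BoneLabel.RADIUS.short].merge(
            radius[key + ["angle_deg"]].rename(columns={"angle_deg": "radius_angle"}),
            on=key,
            how="left",
        )
        if merged["radius_angle"].isna().any():
            raise ValueError("missing radius annotation for some measurements")
        merged["radiocarpal_deg"] = merged["angle_deg"] - merged["radius_angle"]
        return merged


def simulate_session(
    cohort: Sequence[WristPhantom],
    images: Mapping[str, Iterable[str]] | None,
    profiles: Sequence[ObserverProfile],
    session: int,
    seed: int = 0,
    rotation_log: RotationLog | None = None,
) -> MeasurementTable:
    """Simulate one measurement session of the whole observer pool.

    For every observer the wrists are visited in a freshly randomized
    order; each drawn angle equals the ground-truth projected angle (the
    wrist's applied image rotation plus, for carpal bones, the pose-implied
    radiocarpal angle) plus the observer's bias and a Gaussian noise draw.
    ``images`` maps wrist id to the available image kinds (or a mapping of
    kind -> image); pass ``None`` to assume both kinds exist.  An
    instructed observer requires both summation and stripped images; an
    uninstructed observer must not be asked to annotate stripped images.

    The rotation each wrist's images carry is supplied by ``rotation_log``
    (zero if omitted); it offsets every angle-versus-vertical reading of
    that wrist identically and therefore cancels in radiocarpal angles.
    Error draws are independent across sessions, observers, wrists and
    axes.
    """
    if session not in (1, 2):
        raise ValueError("session must be 1 or 2")
    rows = []
    master = np.random.SeedSequence([int(seed), session])
    obs_seeds = master.spawn(len(profiles))
    for profile, oseed in zip(profiles, obs_seeds):
        rng = np.random.default_rng(oseed)
        kinds = profile.image_kinds()
        for wrist in cohort:
            available = None
            if images is not None:
                if wrist.wrist_id not in images:
                    raise ValueError(f"no images for wrist {wrist.wrist_id!r}")
                available = set(images[wrist.wrist_id])
                for kind in kinds:
                    if kind not in available:
                        raise ValueError(
                            f"observer {profile.observer_id!r} needs {kind!r} images, "
                            f"missing for wrist {wrist.wrist_id!r}"
                        )
        order = rng.permutation(len(cohort))
        for idx in order:
            wrist = cohort[idx]
            rotation = (
                rotation_log.rotation_for(wrist.wrist_id) if rotation_log is not None else 0.0
            )
            for kind in kinds:
                for bone in (BoneLabel.RADIUS,) + tuple(MEASURED_BONES):
                    for variant in profile.variants_for(bone):
                        truth = rotation
                        if bone != BoneLabel.RADIUS:
                            truth += wrist.truth_angle(bone, variant.value)
                        sd = profile.noise_sd.get(kind, {}).get(bone, 0.0)
                        drawn = (
                            truth
                            + profile.bias.get(bone, 0.0)
                            + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                        )
                        rows.append(
                            {
                                "wrist_id": wrist.wrist_id,
                                "observer_id": profile.observer_id,
                                "instructed": profile.instructed,
                                "session": session,
                                "bone": bone.short,
                                "variant": variant.value,
                                "image_kind": kind,
                                "angle_deg": drawn,
                            }
                        )
    return MeasurementTable(pd.DataFrame(rows))
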