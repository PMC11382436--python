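import numpy as np
import pytest

from carpalign.axes import (
    AxisConfig,
    DegenerateGeometryError,
    estimate_centroid_axis,
    estimate_lunate_axial_axis,
    estimate_lunate_tangential_axis,
    estimate_metacarpal_axial_axis,
    estimate_radius_axis,
    estimate_tangential_axis,
    locate_distal_articular_surface,
    proximodistal_direction,
)
from carpalign.geometry import rot_flexion, tls_line_fit
from carpalign.phantom import PoseConfig, generate_phantom
from carpalign.volume import BoneLabel, LabeledVolume, MissingBoneError

from conftest import in_plane_angle


def _angle_err(axis, truth_axis) -> float:
    return axis.angle_to(truth_axis)


# -- distal articular surface ------------------------------------------------


def test_radius_distal_face_normal_canonical(neutral_phantom):
    _, n = locate_distal_articular_surface(neutral_phantom.volume, BoneLabel.RADIUS)
    assert np.degrees(np.arccos(np.clip(n @ [0, 0, 1.0], -1, 1))) < 0.5


def test_radius_distal_face_follows_global_tilt():
    pose = PoseConfig(global_rotation=rot_flexion(10.0))
    ph = generate_phantom(pose)
    _, n = locate_distal_articular_surface(ph.volume, BoneLabel.RADIUS)
    expected = rot_flexion(10.0) @ np.array([0.0, 0.0, 1.0])
    assert np.degrees(np.arccos(np.clip(abs(n @ expected), -1, 1))) < 0.5


def test_distal_surface_requires_the_bone(neutral_phantom):
    data = neutral_phantom.volume.data.copy()
    data[data == int(BoneLabel.RADIUS)] = 0
    vol = LabeledVolume(
        data,
        neutral_phantom.volume.spacing,
        neutral_phantom.volume.origin,
    )
    with pytest.raises(MissingBoneError, match="radius"):
        locate_distal_articular_surface(vol, BoneLabel.RADIUS)
    with pytest.raises(ValueError, match="radius or lunate"):
        locate_distal_articular_surface(vol, BoneLabel.CAPITATE)


# -- radius axis -------------------------------------------------------------


def test_radius_axis_on_straight_shaft(neutral_phantom):
    axis = estimate_radius_axis(neutral_phantom.volume)
    truth = neutral_phantom.truth_axes[BoneLabel.RADIUS]["axial"]
    assert _angle_err(axis, truth) < 0.5


def test_radius_axis_ignores_bend_outside_segment():
    """A bend proximal of the 28.8-53.3 mm segment leaves the axis
    unchanged; the straight-case oracle is the analytic shaft axis."""
    spacing = 0.4
    zs = np.arange(-70.0, 1.0, spacing)
    xs = np.arange(-12.0, 12.0, spacing)
    ys = np.arange(-12.0, 12.0, spacing)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    # straight tube of radius 7 for z in [-55, 0]; bent 10 deg beyond z < -55
    bend = np.clip(-(gz + 55.0), 0.0, None) * np.tan(np.radians(10.0))
    inside = (np.hypot(gx, gy - bend) <= 7.0) & (gz <= 0.0) & (gz >= -70.0)
    data = np.where(inside, int(BoneLabel.RADIUS), 0).astype(np.int16)
    vol = LabeledVolume(data, spacing, origin=np.array([xs[0], ys[0], zs[0]]))
    axis = estimate_radius_axis(vol)
    tilt = np.degrees(np.arccos(np.clip(abs(axis.direction @ [0, 0, 1.0]), -1, 1)))
    assert tilt < 0.5


def test_radius_axis_reports_short_shaft():
    ph = generate_phantom(PoseConfig(sizes={"radius_shaft_length": 40.0}))
    with pytest.raises(DegenerateGeometryError, match="mm available"):
        estimate_radius_axis(ph.volume)


def test_segment_length_is_245_mm():
    cfg = AxisConfig()
    lo, hi = cfg.radius_segment
    assert hi - lo == pytest.approx(24.5)


# -- metacarpal --------------------------------------------------------------


def test_metacarpal_axis_recovers_pose():
    ph = generate_phantom(PoseConfig(angles={BoneLabel.MIDDLE_METACARPAL: -10.0}))
    axis = estimate_metacarpal_axial_axis(ph.volume)
    assert in_plane_angle(axis.direction) == pytest.approx(-10.0, abs=0.5)


def test_metacarpal_axis_uses_only_the_proximal_segment():
    """Slices come from the 10 mm proximal segment: the fit must agree with
    an oracle restricted to the same segment even though the distal half of
    the bone is much wider (strong taper)."""
    ph = generate_phantom(PoseConfig(sizes={"metacarpal_tangential_offset": 10.0}))
    axis = estimate_metacarpal_axial_axis(ph.volume)
    truth = ph.truth_axes[BoneLabel.MIDDLE_METACARPAL]["axial"]
    assert _angle_err(axis, truth) < 0.5


def test_metacarpal_too_short():
    ph = generate_phantom(PoseConfig(sizes={"metacarpal_half_length": 3.5}))
    with pytest.raises(DegenerateGeometryError, match="too short"):
        estimate_metacarpal_axial_axis(ph.volume)


# -- centroid axes (scaphoid, capitate) --------------------------------------


@pytest.mark.parametrize("bone", [BoneLabel.SCAPHOID, BoneLabel.CAPITATE])
def test_centroid_axis_on_straight_capsule(posed_phantom, bone):
    axis = estimate_centroid_axis(posed_phantom.volume, bone)
    truth = posed_phantom.truth_axes[bone]["axial"]
    assert _angle_err(axis, truth) < 0.5


def test_centroid_axis_matches_analytic_centroid_oracle():
    """On a gently bent tube the estimate agrees with a total-least-squares
    line through analytically computed slice centroids."""
    spacing = 0.4
    zs = np.arange(-14.0, 14.0, spacing)
    xs = np.arange(-8.0, 8.0, spacing)
    ys = np.arange(-8.0, 10.0, spacing)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    curve = 0.008  # parabolic bend, ~1.4 mm offset at the ends
    inside = (np.hypot(gx, gy - curve * gz**2) <= 4.0) & (np.abs(gz) <= 12.0)
    data = np.where(inside, int(BoneLabel.SCAPHOID), 0).astype(np.int16)
    vol = LabeledVolume(data, spacing, origin=np.array([xs[0], ys[0], zs[0]]))
    axis = estimate_centroid_axis(vol, BoneLabel.SCAPHOID)
    # analytic slice centroids along z
    z_grid = np.arange(-12.0, 12.0, 0.5) + 0.25
    centroids = np.column_stack([np.zeros_like(z_grid), curve * z_grid**2, z_grid])
    _, d_oracle = tls_line_fit(centroids)
    err = np.degrees(np.arccos(np.clip(abs(axis.direction @ d_oracle), -1, 1)))
    assert err < 0.2


def test_centroid_axis_restricted_to_scaphoid_and_capitate(neutral_phantom):
    with pytest.raises(ValueError, match="scaphoid and capitate"):
        estimate_centroid_axis(neutral_phantom.volume, BoneLabel.LUNATE)


def test_slice_thickness_honored(neutral_phantom):
    from carpalign.axes import _slice_centroids

    pts = neutral_phantom.volume.bone_points(BoneLabel.CAPITATE)
    d = proximodistal_direction(neutral_phantom.volume)
    centroids, _ = _slice_centroids(pts, d, 0.5)
    length = (pts @ d).max() - (pts @ d).min()
    assert len(centroids) == pytest.approx(length / 0.5, abs=3)


# -- lunate ------------------------------------------------------------------


def test_lunate_axial_neutral_and_tilted(neutral_phantom):
    axis = estimate_lunate_axial_axis(neutral_phantom.volume)
    assert in_plane_angle(axis.direction) == pytest.approx(0.0, abs=0.5)
    ph = generate_phantom(PoseConfig(angles={BoneLabel.LUNATE: -10.0}))
    axis = estimate_lunate_axial_axis(ph.volume)
    assert in_plane_angle(axis.direction) == pytest.approx(-10.0, abs=0.5)


def test_lunate_axial_requires_lunate(neutral_phantom):
    data = neutral_phantom.volume.data.copy()
    data[data == int(BoneLabel.LUNATE)] = 0
    vol = LabeledVolume(data, neutral_phantom.volume.spacing, neutral_phantom.volume.origin)
    with pytest.raises(MissingBoneError, match="lunate"):
        estimate_lunate_axial_axis(vol)


def test_lunate_tangential_rotates_with_the_bone(neutral_plane):
    for pose_angle in (0.0, 10.0):
        ph = generate_phantom(PoseConfig(angles={BoneLabel.LUNATE: pose_angle}))
        plane = neutral_plane
        axis = estimate_lunate_tangential_axis(ph.volume, plane)
        truth = ph.truth_axes[BoneLabel.LUNATE]["tangential"]
        assert _angle_err(axis, truth) < 1.0


def test_lunate_tangential_needs_two_horns(neutral_plane):
    ph = generate_phantom(
        PoseConfig(sizes={"lunate_horn_radius": 0.25, "lunate_horn_lift": 0.1})
    )
    with pytest.raises(DegenerateGeometryError, match="horn"):
        estimate_lunate_tangential_axis(ph.volume, neutral_plane)


# -- margin tangents ---------------------------------------------------------


@pytest.mark.parametrize(
    "bone", [BoneLabel.SCAPHOID, BoneLabel.CAPITATE, BoneLabel.MIDDLE_METACARPAL]
)
def test_tangential_axis_recovers_constructed_offset(posed_phantom, posed_plane, bone):
    axis = estimate_tangential_axis(posed_phantom.volume, bone, posed_plane)
    truth = posed_phantom.truth_axes[bone]["tangential"]
    assert _angle_err(axis, truth) < 1.0


def test_capitate_tangential_separates_from_axial(posed_phantom, posed_plane):
    """Capitate posed at -13 with an 11 deg dorsal taper reads about -24 on
    the tangent, mirroring the axial/tangential split of real wrists."""
    from carpalign.projection import project_axis, signed_angle
    from carpalign.axes import estimate_radius_axis

    r2 = project_axis(estimate_radius_axis(posed_phantom.volume), posed_plane)
    t2 = project_axis(
        estimate_tangential_axis(posed_phantom.volume, BoneLabel.CAPITATE, posed_plane),
        posed_plane,
    )
    assert signed_angle(r2, t2) == pytest.approx(-24.0, abs=1.0)


def test_tangential_axis_rejects_shapes_without_a_spanning_tangent():
    # a large sphere has no support line touching both of its thirds
    from carpalign.projection import LateralPlane

    spacing = 0.4
    xs = np.arange(-17.0, 17.0, spacing)
    gx, gy, gz = np.meshgrid(xs, xs, xs, indexing="ij")
    inside = gx**2 + gy**2 + gz**2 <= 15.0**2
    data = np.where(inside, int(BoneLabel.CAPITATE), 0).astype(np.int16)
    vol = LabeledVolume(data, spacing, origin=np.array([xs[0]] * 3))
    plane = LateralPlane(
        origin=np.zeros(3), u=[0.0, 0.0, 1.0], v=[0.0, 1.0, 0.0], normal=[-1.0, 0.0, 0.0]
    )
    with pytest.raises(DegenerateGeometryError, match="thirds"):
        estimate_tangential_axis(vol, BoneLabel.CAPITATE, plane)


def test_tangential_axis_rejects_undefined_bones(neutral_phantom, neutral_plane):
    with pytest.raises(ValueError, match="margin tangent"):
        estimate_tangential_axis(neutral_phantom.volume, BoneLabel.LUNATE, neutral_plane)
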