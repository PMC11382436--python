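"""Render reconstructed radiographs and recover the applied rotation.

Renders a lateral summation image and a scaphoid-only stripped image from
a phantom volume, applies the study protocol's pseudorandom 1-10 degree
in-plane rotation, then measures the radius axis versus the image vertical
on a radius-only render.  The measured angle minus the logged rotation is
the radius-axis measurement error, which should be a small fraction of a
degree for this noiseless "annotator".
"""
from carpalign import (
    assign_rotations,
    define_spc_lateral_plane,
    estimate_dominant_axis_angle,
    generate_phantom,
    radius_axis_error,
    render_stripped,
    render_summation,
    rotate_in_plane,
)
from carpalign.volume import BoneLabel

phantom = generate_phantom(seed=0, wrist_id="demo")
volume = phantom.volume
plane = define_spc_lateral_plane(volume)

log = assign_rotations(["demo"], seed=4)
theta = log.rotation_for("demo")

summation = rotate_in_plane(render_summation(volume, plane, wrist_id="demo"), theta)
stripped = rotate_in_plane(
    render_stripped(volume, plane, BoneLabel.SCAPHOID, wrist_id="demo"), theta
)
radius_only = rotate_in_plane(
    render_summation(volume, plane, {BoneLabel.RADIUS}, wrist_id="demo"), theta
)

drawn = estimate_dominant_axis_angle(radius_only)
print(f"summation image: {summation.pixels.shape}, bones {len(summation.included_bones)}")
print(f"stripped image bones: {sorted(b.short for b in stripped.included_bones)}")
print(f"applied rotation: {theta:.3f} deg")
print(f"measured radius axis vs vertical: {drawn:.3f} deg")
print(f"radius-axis error: {radius_axis_error(drawn, log, 'demo'):+.3f} deg")
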