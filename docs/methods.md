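# Methods

`carpalign` re-creates, end to end, a computer-aided carpal-alignment
measurement pipeline and the apparatus needed to validate one: a synthetic
wrist phantom with analytic ground truth, the measurement chain itself
(per-bone 3D axes, lateral-plane projection, signed angles), digitally
reconstructed radiographs, simulated human observers, and the reliability
statistics of observer studies.  This note records the models, the
numerical choices, and what the validation does and does not demonstrate.

## Coordinate and sign conventions

World frame: `x` radioulnar, `y` dorsopalmar (palmar positive), `z`
proximodistal (distal positive).  All angles are signed with flexion —
palmar angulation of the distal bone relative to the radius axis —
positive.  Under this convention a normally flexed scaphoid reads around
+50°, while capitate and middle metacarpal read slightly negative
(extended), matching the sign structure of published normal values.
Radiographic images place rows distal-ascending and columns
palmar-ascending, so an axis leaning palmar at its distal end reads a
positive angle against the image vertical.

## The wrist phantom

Each bone is a solid with an unambiguous analytic axis:

* **Radius** — a tapered round cone (convex hull of two spheres, proximal
  radius 6 mm, distal 8.5 mm, shaft 58 mm) cut flat at the distal
  articular face, with a label-free medullary canal bored along the shaft.
* **Scaphoid, capitate, middle metacarpal** — tapered round cones.  The
  taper realizes the axial/tangential variant separation: the palmar or
  dorsal silhouette tangent of a round cone is the external bitangent of
  its two end circles, tilted by `arcsin((r_d − r_p) / 2h)` from the long
  axis.  Because the solids are axisymmetric, slice centroids lie exactly
  on the axis, so the axial truth is exact while the tangential truth
  differs by exactly the configured offset (defaults −5° scaphoid, −11°
  dorsal capitate, +7° dorsal metacarpal — the offsets implied by the
  study population's axial-versus-tangential means).  The metacarpal's
  proximal (carpometacarpal) base is cut flat, as in the real bone.
* **Lunate** — a crescent: a 7 mm sphere minus a 9 mm carving sphere
  offset 8 mm distally, leaving a concave distal articular cup with a rim
  circle, plus two small horn spheres (radius 2 mm) seated just outside
  the rim so the projected silhouette shows two distal horn tips.  The
  horn pair is tilted by the lunate's tangential offset (default +2°).
  Keeping the horns radially outside the rim matters: horns that bite into
  the cup bias the cup-plane fit by over a degree.
* **Pisiform** — a small ellipsoid, needed only for the
  scaphopisocapitate (SPC) plane.

Bones are posed by per-bone flexion/extension rotations about their own
centers, then an optional global rigid transform.  The scaphoid, pisiform
and capitate centers share the sagittal plane `x = 0` and every primitive
is mirror-symmetric about its own sagittal plane, so the plane through the
three centroids is exactly the lateral plane for every pose; the lunate
occupies its own radioulnar lane so its sphere cannot collide with the
sagittal bones.  The layout was chosen so that no two bones overlap
anywhere within ±3 SD of the default cohort pose distribution; overlap is
still checked voxel-by-voxel at generation time and raises an error naming
the colliding pair.  One consequence of collision-free spacing is that the
canonical phantom does *not* reproduce the radiographic SPC view-quality
criterion (pisiform palmar cortex between the scaphoid and capitate palmar
cortices); the SPC plane here is operationalized through the three
centroids, for which only their positions matter.

Cohort pose angles are drawn per bone from normal distributions; the
defaults are the software-measured population values (radioscaphoid 54
(SD 11), radiolunate 0 (13), radiocapitate −13 (7), radiometacarpal −9 (7)
degrees).  Draws are clipped at ±89° (beyond ±4 SD at the defaults).
Ground-truth axes are analytic, so cohorts of any size can be summarized
without voxelization; volumes are voxelized lazily at 0.4 mm isotropic
spacing by default (a typical cone-beam CT order; no voxel size is implied
by the validated software).

What the phantom does *not* emulate: anatomically realistic bone shapes,
soft tissue, image noise, beam hardening, segmentation errors.  Passing
the validation therefore shows that the measurement chain is correct and
stable given a clean segmentation — not that any particular segmenter is.

## Axis estimation

* **Distal reference.** "Distal" is derived from the volume itself — the
  radius principal axis oriented toward the carpal centroid — so every
  estimator is equivariant under arbitrary rigid transforms of the whole
  wrist.
* **Radius** — total-least-squares line through cross-section centroids of
  the shaft between 28.8 mm and 53.3 mm proximal of the distal articular
  face (a 24.5 mm segment).  The face itself is a plane fitted to the
  most-distal surface voxels, with the selection band iterated so it
  follows the face under tilt.
* **Scaphoid, capitate** — line through the geometric centers of 0.5 mm
  slices along the bone, resliced perpendicular to the first principal
  axis (single pass; whether the validated software iterates is unknown,
  so the PCA-initialized single pass is the declared choice).  "Geometric
  center" is read as the voxel-count centroid of a slice.
* **Middle metacarpal** — centroid line of a 10 mm segment of the proximal
  metaphysis/diaphysis, anchored by excluding a 2 mm proximal articular
  cap (the protocol does not define the segment's start; this convention
  is ours).
* **Lunate axial** — axis through the centroid, perpendicular to the
  distal articular surface.  The cup is found by fitting a sphere to the
  body surface and classifying samples lying well inside it as articular
  cup; a second iterated sphere fit cleans the cup of horn-crease
  samples.  The axis averages two independent reads — the cup cap's
  best-fit plane normal and the body-center-to-cup-center direction —
  which roughly halves the orientation noise of either alone.
* **Tangential axes** — computed on the 2D projected silhouette (their
  manual counterparts are 2D constructions).  The convex hull is scanned
  with a rotating support direction on the required margin; the support
  line must touch both the proximal and distal thirds of the silhouette's
  extent along its own long axis, otherwise the shape is rejected.  The
  lunate's tangential axis is the in-plane perpendicular to the line
  joining its two distal horn tips, found as local maxima of the
  silhouette top profile scanned in a cup-axis-aligned frame.

### Numerical choices that matter at 0.4 mm voxels

Several estimators needed sub-voxel machinery to stay inside a 1° error
budget; these are deliberate design choices, stated here because naive
versions fail quietly:

* **Anti-aliased slicing.**  Hard 0.5 mm slice boundaries beat against the
  0.4 mm voxel lattice and chop voxel layers into crescents whose
  centroids oscillate off-axis by several tenths of a millimeter; voxels
  are therefore assigned to slices with a triangular kernel, and the line
  fit weights slices by their effective voxel count.  Measurement segments
  keep only slices whose kernel support lies fully inside the segment, so
  no obliquely cut end slice with a strongly off-axis centroid enters the
  fit (on the short 10 mm metacarpal segment such end slices alone caused
  errors near 2°).
* **Support-line touch band.**  Voxelization turns the ideal single
  bitangent hull edge into a staircase of near-collinear edges, so
  tangency is assessed with a one-voxel band and the thirds test carries a
  two-voxel allowance for the eroded contact arcs.
* **Surface-crest refinement.**  The voxel-limited support line is refined
  by a linear least-squares fit of the 3D surface crest,
  `b ~ 1 + a + x + x² + a·x² + a·x` (`a` along the margin, `b` outward,
  `x` out-of-plane); the `a·x²` term absorbs the bone's taper.  Surface
  voxels sample the crest at many out-of-plane offsets and quantization
  phases, bringing the tangent error to ~0.15° RMS.
* **Sub-voxel surface samples for the lunate.**  The lunate's fits operate
  on surface samples obtained by projecting transition-band voxels of the
  Gaussian-smoothed mask onto its 0.5 isosurface along the local gradient
  (displacements clamped to ~one voxel; flat-gradient voxels dropped).
  This cuts per-orientation noise of the cup normal roughly three-fold.
* **Horn-tip localization.**  The top profile is padded with a low
  sentinel so a horn at the silhouette border still registers as a peak,
  and tips are refined iteratively as centroids of each horn's distal cap
  under a threshold shared by both horns in a frame aligned with the
  current tip line — the shared threshold makes the two centroid offsets
  identical, so they cancel in the tip-line direction.

Measured on 60 random phantoms with poses up to ±30°, the estimators
recover every axis within 0.8° of ground truth (0.13° RMS over all
angles), and full radiocarpal angle sets change by at most ~0.46° under
random whole-wrist rigid transforms.

## Lateral projection and angles

The SPC lateral plane is the plane through the scaphoid, pisiform and
capitate centroids — a constructive surrogate for the radiographic SPC
alignment criterion, which is a view-quality check rather than a plane
definition.  Its in-plane basis is `u` (radius axis direction projected
into the plane, distal positive) and `v` (palmar positive, the sign fixed
by the pisiform's palmar position).  Axes are orthogonally projected
(rejected if within 5° of the plane normal) and the radiocarpal angle is
the signed rotation from the projected radius direction to the projected
bone direction.  Angles are kept at 0.1° precision internally; report
output rounds to integer degrees.

## Reconstructed radiographs

Summation images integrate material path length along rays parallel to the
plane normal — uniform path-length weighting, no attenuation physics (the
validated system's weighting is unpublished; this is the declared model).
Each voxel deposits its volume into the pixel containing its projected
center, which makes rendering exactly linear in the included bone set and
reproduces analytic path lengths for aligned solids.  Stripped images
include only the target carpal bone plus radius and middle metacarpal.
Every wrist receives one pseudorandom in-plane rotation drawn uniformly
from 1–10°, reused for all of its images; rotations are logged so the
radius-axis-versus-vertical reading can be scored against the known value.
In-plane rotation pads the canvas before resampling (bilinear), so no
content is clipped; a rotate/unrotate round trip leaves a mean absolute
pixel error of ~0.1 mm path length, with worst-case errors of a few mm
confined to bone edges.

## Observer simulation

Observer error is additive Gaussian on the measured angle (the downstream
statistics consume angles only), with optional per-bone systematic bias
(default zero — the study quantifies none).  Uninstructed observers read
only summation images with one self-chosen axis per bone; in the default
pool of seven, all prefer the axial axes except one who draws tangential
scaphoid and lunate axes.  Instructed observers (default six) read both
variants on both image sets.  Each observer reads every wrist in two
sessions with freshly shuffled order and independent error draws.  Default
noise SDs (per bone and image kind, e.g. scaphoid 4.0° on summation
versus 1.6° on stripped images, radius below 1°) are a *calibration*
chosen so the simulated pools land in realistic reliability territory —
high-0.8s to mid-0.9s ICCs on summation images, ≥0.95 on stripped images —
not an estimate from data.

## Reliability statistics

ICC(2,1) — two-way random effects, absolute agreement, single measures —
is computed directly from the two-way ANOVA mean squares,
`(MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))`; no mixed model is
fitted and no confidence intervals are produced.  A zero-variance ratings
matrix raises an error (the ICC is undefined).  Categories: poor < 0.5,
moderate 0.5–0.75, good 0.76–0.9, excellent > 0.9; the gap between 0.75
and 0.76 resolves to "good" (closed lower bound as printed).

Intra-observer reliability is the per-observer wrists × sessions ICC,
summarized across observers as mean (SD; range); inter-observer
reliability is a single wrists × observers ICC on session 1, computed
separately per observer group.  Because uninstructed observers each drew a
single self-chosen axis, their group is assembled per bone with observers
pooled across preferred variants; the instructed group keeps the
axial/tangential split.

Bland–Altman agreement reports the mean difference (first minus second;
observer mean minus software in the comparison report), its SD, and
limits of agreement at mean ± 1.96 SD; a 2 SD band is also emitted, the
1.96 limits being canonical.  Pairs with |difference| > 20° are flagged as
outliers — the rule that exposed a segmentation failure in the original
validation.  Paired comparisons use the two-sided Student's t-test and
rank correlation Spearman's test (average ranks), both through
`scipy.stats` with significance at 0.05 and no multiple-testing
correction; a perfectly constant nonzero paired difference is reported as
p = 0 rather than an error in the variant-comparison report.

The closed-form link between session disagreement and test–retest
reliability: with independent per-session errors N(0, s²), the mean
absolute between-session difference is `2s/√π`, so a target difference d
calibrates `s = d·√π/2`.  At a between-wrist SD of 11° (the radiolunate
population SD, the only printed SD that reproduces the quoted
relationship), a 5° mean absolute difference gives ICC ≈ 121/(121 + 25π/4)
≈ 0.860; `scripts/acceptance.py` recomputes this by simulation with
10,000 wrists.

## Problem sizes used in validation

The test suite runs: axis recovery on 100 random phantoms (|poses| ≤ 30°,
0.4 mm voxels); rigid invariance over 5 phantoms × 20 random rigid
transforms; rotation-protocol recovery over a 30-wrist cohort; a 4-wrist
end-to-end byte-determinism run of the full command-line pipeline; and
10,000-wrist simulations for the ICC asymptotics.  These sizes were chosen
to exercise every claim at meaningful scale while keeping the whole suite
in the minutes range.

## Known limitations

* Phantom bones are geometric primitives; estimator behavior on real
  segmented anatomy (irregular cortices, osteophytes, segmentation noise)
  is outside what these tests can show.
* The summation renderer ignores attenuation; image realism is limited to
  geometry.
* Observer noise is angle-additive and Gaussian; real annotation errors
  are landmark-driven and may be skewed or bone-pose-dependent.
* ICC forms other than (2,1) and confidence intervals for ICCs are not
  provided.
* The tangential-axis estimator requires a silhouette whose margin tangent
  touches both end thirds; highly spherical shapes are rejected rather
  than measured.
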