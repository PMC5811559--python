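# Methods

This note documents the models, conventions, parameter choices and
known limitations of panomap, in the order the pipeline runs.

## Coordinate and camera conventions

World units are those of the calibration cuboid — inches for the
default rabbit-scale target — and the world origin is the cuboid
center, +z up along the rotation (cannula) axis. Cameras look down
their +z axis; pixel coordinates are 0-based with u right, v down and
pixel centers at integer coordinates; image row 0 is the top of the
image. The camera viewing direction N_ic is `Rᵀ(0,0,1)`.

The projection model is `p_c = R p + t`, `x = X/Z`, `y = Y/Z`,
`x' = x(1 + k1 r²)` (and likewise y'), `u = f x' + u0`,
`v = s f y' + v0`. A single radial coefficient `k1` is carried but
frozen at 0 by default — rigs of this type use long working distances
where distortion is negligible — and can be freed during calibration
with `estimate_k1=True`.

## Calibration target and junction handling

The cuboid (L × W × H = 1 × 1 × 2, configurable) carries grid lines on
its four vertical faces at 0.25-inch spacing, inset half a spacing from
the face edges, giving a 4 × 8 junction lattice per 1 × 2 face. A
corner-on camera therefore sees exactly 64 junctions on its two visible
faces. The spacing itself is a package choice: only the target
dimensions and the 64-junction count are fixed by the rig design, and
this is the unique half-spacing-inset layout consistent with both.

**Detection** runs a Harris corner detector inside a user (or fixture)
supplied target mask. A crossing of two thick dark lines excites up to
four sub-corner responses around the true junction, so the detector
estimates the grid pitch from 5th-neighbor distances, refines every
response with `corner_subpix` using a window of ~0.8 pitch (which
pulls all siblings of one crossing onto its saddle point), and
collapses them by single-linkage clustering at 0.4 pitch. Two smoothing
scales are tried and the most grid-regular result (lowest
nearest-neighbor spacing CV, with an optional expected-count prior)
wins. This works from ~6 px grid pitch (100 × 100 optical cameras)
up to large geometry-camera images.

**Labeling** reconstructs the row/column lattice (rows split at the
largest gaps in v, columns ordered by u — valid for the near-equatorial
viewing the rig geometry implies) and then either: (a) with two corner
anchors, mirrors the interactive workflow in which the user names the
top-left and bottom-right visible junctions, propagating indices along
the lattice; or (b) without anchors, scores every adjacent-face-pair ×
orientation hypothesis by the reprojection RMSE of a DLT camera fit,
rejecting reflected (improper) hypotheses outright and preferring an
upright camera among ties. Because the uniform-grid cuboid has a
nontrivial proper symmetry group (rotations about z; 180° end-over-end
flips), unanchored labels are recoverable only up to that symmetry;
the resulting camera is equally valid, and anchors pin the frame when
absolute orientation matters (the pipeline always anchors).

**Optimization** seeds from a 6+-point DLT (projection matrix by SVD,
rescaled so its camera-z row has unit norm, RQ-split into intrinsics
and a proper rotation) and refines rotation (as a rotation vector),
translation, f, s, u0, v0 (and optionally k1) with
`scipy.optimize.least_squares(method="lm")` on the stacked 2D
reprojection residuals, tolerances 1e-14, up to ~200 iterations'
worth of function evaluations. Junction world coordinates are treated
as exact (no bundle adjustment).

## Silhouettes and visual-hull carving

Rotation images are segmented by Otsu thresholding (heart darker than
the backdrop; a polarity flag flips this), polygon add/remove edits,
morphological hole filling — interior specular highlights otherwise
punch holes that would corrupt carving — and largest-component
selection. The stage convention is: at stage angle a, a body point p
sits at `R_axis(a)·p`; the silhouette renderer and the carver share
this convention, and carving projects `R_axis(a)·p` into the
silhouette taken at angle a.

The carver subdivides a cube (default 1.2× the largest back-projected
silhouette extent, centered on the axis) to `2^max_depth` cells per
edge (default depth 7, i.e. 128³). A naive octree that finalizes a
coarse voxel whenever its 8 corners agree is *not* equivalent to
classifying the finest grid — corner membership does not bound the
interior. Coarse cells are therefore finalized only when a
distance-transform argument proves the whole cell shares the
classification: the cell center is projected into each silhouette, and
the Euclidean distance transform value at that pixel is compared with
the projected cell circumradius `r·f·max(s,1)/(Z − r)` plus a 1.5 px
rounding margin. Anything unproven is subdivided, and at the finest
level the exact rule applies: a corner is inside iff its nearest-pixel
projection lands on the silhouette in *every* view (off-image counts
as outside); all-8-inside ⇒ 1, all-outside ⇒ 0, mixed ⇒ ½. The result
is cell-for-cell identical to the brute-force `carve_dense`, which the
tests verify at depths 3–5.

Boundary cells enter the occupancy as ½ so the iso-0.5 marching-cubes
surface passes through them; marking them inside would bias the hull
outward by a full voxel. The field is sampled at cell centers and
zero-padded before marching cubes; the mesh is cleaned (duplicate
vertices, degenerate faces), consistently wound to positive signed
volume, and optionally relaxed by Taubin λ|μ smoothing (defaults 50
iterations, λ = 0.5, μ = −0.53), which keeps enclosed volume within
~1–2 % unlike plain Laplacian smoothing.

Visual-hull caveat: the hull is a superset of any non-convex object
(concavities invisible in silhouettes are filled), and discretization
trims a skin of about one voxel diagonal plus one back-projected pixel
(~0.01 world units at the default geometry) from the guarantee that
interior points survive carving.

## Signal conditioning

The chain runs normalize → 3×3 bin → FIR → detrend (order switchable;
normalization-first mirrors the interactive workflow even though
filtering-first is arguably cleaner). All stages preserve shape and
mask and never let background pixels contaminate foreground averages.

* Normalization is per-pixel min–max over time (the optical-mapping
  standard; fluorescence baselines vary strongly across tissue).
  Constant traces are demoted to background with a warning.
* The temporal filter is a Hamming-windowed linear-phase FIR, order
  100 (101 taps), band 0–100 Hz; the zero lower edge makes the
  band-pass a low-pass. It is applied centered (edge-replicated), so
  group delay is exactly compensated and DC gain is 1. The sampling
  rate is required configuration — it is a property of the acquisition
  hardware, and typical voltage-dye systems run at 1 kHz, the value
  used throughout the tests.
* First-order drift removal subtracts the per-pixel least-squares line
  and restores the mean. Note the subtlety that a finite sinusoid
  record is only *exactly* orthogonal to a line when it is even about
  the record midpoint over whole periods; detrending distorts a
  low-frequency oscillation by O(A/ωT) otherwise.
* The blending weight mask is `w = 0.5 + 0.5·(d − d_min)/(d_max −
  d_min)` with d the distance to the nearest background pixel, so the
  outermost foreground pixels get exactly 0.5 and the deepest pixel
  exactly 1 (a uniform-depth mask gets 1). The linear-in-depth form is
  a package choice; only the endpoint values are fixed by the rig's
  processing convention.

## Texture mapping

Face visibility is decided purely by the angle θ between the unit face
normal and N_ic: θ < 90° excluded, 90° ≤ θ ≤ 115° edge (closed
interval), θ > 115° assigned. No z-buffer test is applied — correct
for the convex-ish epicardium, and faces in concavities would at worst
blend cameras that see nearly the same tissue. Centroids are projected
and rounded to the nearest pixel ("closest pixel"); projections
outside the frame, behind the camera, or landing on a camera's
background mask do not contribute. One contributor: the trace is
copied verbatim. Several: the blend is `Σ wᵢ sᵢ / Σ wᵢ` with wᵢ the
weight-mask value at the projected pixel, making every blended trace a
convex combination of camera traces. A face is `overlap` when ≥ 2
cameras view it at θ > 115°, `edge` when only grazing views
contribute, `excluded` (signal = NaN) when none do.

## Electrophysiology maps

* **Activation**: time of the maximum first difference within the
  analysis window, refined by a parabolic fit over the derivative peak
  (clamped to ±half a sample); a 50 %-crossing alternative sits behind
  `method="midpoint"`. Flat traces are missing.
* **APD**: first time after the AP peak that the trace falls below
  `peak − level·(peak − baseline)` (baseline = trace minimum), linearly
  interpolated, minus the activation time; level 0.8 gives APD80.
  Invariant to affine trace rescaling by construction.
* **Dominant frequency**: Welch periodogram peak within 0.5–50 Hz,
  `nperseg = min(T, max(256, T/2))`; ≥ 2 s records recommended for
  sub-Hz resolution.
* **Phase**: angle of the analytic signal (Hilbert transform) of the
  mean-subtracted trace, wrapped to (−π, π].
* **Phase singularities**: sum of the four wrapped phase differences
  around every 2 × 2 pixel loop; ±2π (tolerance 1e-6) marks a charge
  of that sign at the loop center. Charges are exactly ±1 by
  construction of the wrapped sum. Detection runs on 2D rasters
  (camera frames or unwrapped maps); mesh-loop detection is an
  extension point. The phase and PS algorithms are the field-standard
  choices; the original interactive tool does not document its own.

## Map unwrapping

Face centroids, translated to the mesh centroid, get longitude λ
(azimuth about the rotation axis) and latitude φ (elevation from its
equatorial plane). Mercator (`x = λ, y = ln tan(45° + φ/2)`, latitude
clamped at ±85° with the polar caps reported missing) preserves local
shape; Hammer (`x = 2√2 cosφ sin(λ/2)/D`, `y = √2 sinφ/D`,
`D = √(1 + cosφ cos(λ/2))`) preserves areas — the numerical Jacobian
test confirms det J/cosφ constant to well under 1 %. Raster pixels
take the value of the face whose direction is nearest on the unit
sphere — nearest-face sampling, not interpolation, so isochrone
discontinuities stay sharp and every raster value equals some face
value. For a strongly non-spherical or non-star-shaped surface this
centroid-direction parameterization can fold (two faces sharing a
direction); the hearts this rig images are star-shaped about the
cannula axis in practice.

## Synthetic fixtures

The generators stand in for the rig: ray-cast cuboid renders
(supersampled 3×, line half-width 0.02 in, with exact projected
junction truth), exact ray-traced silhouettes of spheres, ellipsoids
and cuboids, and optical movies made by ray casting a mesh-borne
signal field into each camera. The default scene mirrors the physical
rig: four 100 × 100 optical cameras at 90° azimuth spacing and 8 in
distance, one 160 × 160 geometry camera, all calibrated corner-on to
the cuboid from their experiment poses. The action potential is
piecewise linear (2 ms upstroke, 80 ms plateau, 100 ms linear
repolarization by default) because its APD at any level has a closed
form — ground truth beats biophysical realism for validation. The
plane-wave speed defaults to 20 in/s (~0.5 m/s, paced ventricular
conduction); movies default to 1 kHz with σ = 0.02 additive Gaussian
noise. What the fixtures do *not* emulate: optics blur and vignetting,
photon noise statistics, motion, dye photobleaching beyond a linear
trend, and genuinely concave anatomy (atrioventricular grooves) —
passing tests demonstrate algorithmic correctness on star-shaped
geometry and clean optics, not robustness to those effects.

The end-to-end check carves an ellipsoid (semi-axes 1 × 1 × 1.3 in)
from 72 silhouettes at octree depth 6, projects four-camera plane-wave
movies (450 ms at 1 kHz), and compares the recovered activation map
with the analytic ground truth; the pipeline summary used in the
README is:

```python
st = bundle.state
mesh, act = st["mesh"], st["activation_map"].values
ok = np.isfinite(act)
z = mesh.face_centroids[:, 2]
r = np.corrcoef(z[ok], act[ok])[0, 1]
slope = np.polyfit(z[ok], act[ok], 1)[0]
print(f"mesh               : {mesh.n_cells} faces, volume {mesh.enclosed_volume:.2f} in^3")
print(f"faces with signal  : {100*ok.mean():.1f} %")
print(f"activation vs axis : r = {r:.4f}, slope {slope:.1f} ms/in (true 50.0)")
print(f"calibration RMSE   : {st['calibration_rmse_px']['A']:.2f} px")
```

Problem sizes throughout the tests (carve depths 4–7, 24–72 views,
300–450 ms records, icosphere subdivisions 2–3) were chosen as the
smallest scenes that exercise each contract meaningfully.

## Known limitations

* Visual hulls cannot recover concavities; enclosed volume is biased
  high for real hearts.
* The rotation axis is assumed registered to the world frame (cannula
  through the calibrated origin); axis misregistration is configurable
  but not estimated.
* Labeling assumes grid rows do not overlap vertically in the image
  (near-equatorial cameras); strongly tilted calibration views would
  need anchor-guided or homography-based lattice recovery.
* Junction detection needs a projected grid pitch of roughly ≥ 6 px;
  smaller targets in frame defeat the corner detector.
* No rotor trajectory linking, conduction-velocity vector fields or
  restitution analysis; these are deliberate non-goals.
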