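# Methods

This note records the models, conventions and numerical choices behind
`mskwarp`, and what its synthetic tests do and do not establish about real
data.

## The landmark template

The template is a parametric simplified skeleton, not a digitized bone
atlas: landmark *names*, *counts*, *segment assignment* and the
primary/secondary *tier split* (21 + 85 bone landmarks, 4 joint-center
doubles) are the meaningful structure; positions are plausible adult
coordinates built to be exactly symmetric across the sagittal plane.  The
femur and tibia constructors take torsion, neck-shaft and tibial-torsion
angles as parameters and place landmarks so that the package's own
measurement definitions read those angles back exactly — this is what makes
construct-and-measure oracles possible.  Template defaults: 12°
anteversion, 125° neck-shaft, 15° external tibial torsion, 0.42 m femur,
0.40 m tibia.

Anyone replacing the template with a digitized one only needs to preserve
the landmark names used by the frame recipes and measures (ASIS/PSIS,
femoral head center, epicondyles, condyles, malleoli, neck base, shaft
points, the pelvis dimension landmarks).

## Coordinate frames and units

Internal canonical coordinates are ISB-style global: x anterior, y superior,
z right, meters.  Slicer markups arrive in RAS (or LPS, sign-flipped on
read) millimeters; conversion to ISB is a fixed rotation documented in
`slicer_io` (ISB x = RAS −y, ISB y = RAS +z, ISB z = RAS +x, a supine-scan
convention) plus mm→m scaling, overridable per scanner via `axis_map`.  No
coordinate system is ever assumed silently: files without a declaration are
rejected.

Segment frame recipes (primary axis kept exact, secondary orthogonalized):
pelvis from ASIS/PSIS midpoints; femur origin at the hip center with y
toward the hip from the epicondyle midpoint; tibia from condyle and
malleolus midpoints; patella from apex/base/borders.  The foot has no
template landmarks, so its frame reuses the tibia rotation translated to the
ankle center — a deliberate simplification; the foot only carries distal
muscle insertions.

## Thin-plate spline

Kernel `U(r) = r` (3D biharmonic form).  Because this kernel is
conditionally *negative* definite, the penalized normal equations carry the
ridge with a minus sign, `(K − λI)W + PA = T`, and the bending energy is
`−trace(WᵀKW)`; both signs were verified against the defining monotonicity
property (landmark residual non-decreasing and energy non-increasing in λ).

The ridge is **not** rescaled by the landmark count.  An N-proportional
ridge (`NλI`), with N = 110 landmarks and λ = 0.001 interpreted in meters,
over-smooths enough to bias recovered joint centers by ~1 mm and segment
lengths by ~0.2% on noise-free synthetic participants; the un-normalized
form keeps those errors below 0.1 mm / 0.01% while still providing the
intended noise robustness at the published penalty levels (0.001 for
points, 0.02 for display surfaces).  λ is expressed in the units of the
solve (meters).

One spline is fitted per participant from **all** homologous bone-landmark
pairs and applied to muscle points, joint centers, wrap-surface positions
and skin markers; a second fit from the same pairs at the surface penalty
warps display meshes.  Wrap radii, lengths and axis orientations are never
warped — only translated — matching the convention that analytic wrap
geometry is preserved from the generic model.

Degenerate (coplanar/collinear) landmark configurations are rejected via the
singular values of the centered source cloud (relative threshold 1e-10).

## Muscle mechanics

Path length is polyline length except across segments assigned a wrap
cylinder: if the straight segment penetrates the cylinder (2D point-segment
distance to the axis below the radius, with both endpoints outside — an
endpoint inside is an error, never silently handled), it is replaced by the
tangent–arc–tangent geodesic.  On a cylinder the geodesic is a helix, so
the 3D length is `sqrt(L2d² + Δz²)` with `L2d` the in-plane
tangent–arc–tangent length.  The wrap side is chosen by the cylinder's
`active_quadrant` tag (the side whose arc midpoint points into the named
local direction), with the shorter path as tie-break.  Single-cylinder
wrapping only; spheres/ellipsoids are out of scope.

Moment arms use the tendon-excursion method, `r(θ) = −dL/dθ`, central
differences with Δθ = 0.5° by default (one-sided at joint-range ends).
Truncation error at 0.5° is ~3×10⁻⁶ relative for smooth paths; analytic
oracle tests use Δθ = 0.05°.

The via-point objective is `dmean + dmax + dshape + dshift + pdrop`:
mean/max absolute waveform difference, end-to-end height difference,
a via-displacement regularizer, and a count of sudden adjacent-sample drops
(default threshold 15% of the waveform's max magnitude, weight 1 per
interval — one wrap-induced collapse dominates all dmean-scale terms).
`dshift` is implemented as (weight × Euclidean displacement of the moved
point from its warped initial position); the weight defaults to 0.1 and is
set to 0 in tests that recover a constructed known optimum, where the
initial position is by construction wrong.  The optimizer is a seeded
Nelder-Mead restarted from the initial point plus two seeded starts inside
the search ball, run per movable point distal-to-proximal; every candidate
displacement is projected onto the search ball before evaluation, so the
radius bound is enforced exactly, and a result worse than the input model is
discarded (the objective never increases).

The wrap-radius rule: any cylinder with a neighbouring path point closer to
its axis than its radius has the radius reduced to `safety × min(axis
distances)` (safety 0.98).  The rule is idempotent and leaves zero
violations by construction.

## Strength scaling

`V = 47·mass·height + 1285` predicts *total* lower-limb muscle volume in
cm³ from kg and m (the constants are unit-bound).  Per-muscle volumes are
allocated by the generic model's volume fractions — uniform fractions when
none are given — so the volume ratio is the same for every muscle and the
force factor reduces to the fiber-length correction on top of it.
Optimal-fiber-length scaling under linear segment scaling uses the
geometric mean of the spanned segments' mean scale factors.  Linear scaling
itself is applied in segment-local frames and re-chained root-down so
scaled segments stay connected at their joint centers.

## Shape statistics

GPA: center, scale each configuration to unit centroid size, rotate to the
evolving mean by orthogonal Procrustes with reflections disallowed
(det = +1 enforced), iterate to 1e-10.  "Standardization" is centroid-size
normalization, not per-coordinate z-scoring.  PCA is an SVD of the centered,
flattened aligned coordinates; variance fractions are normalized squared
singular values over the numerically non-null rank, so they sum to 1 and
reconstruction from all scores is exact to floating point.  Waveform peaks
split stance at 50% (early/late); the split is a parameter.

## Synthetic data

Synthetic participants are deformations of the template built from exactly
the pieces a TPS with 110 anchors can represent: a random affine part
(uniform scale from `scale_range`, default 0.95–1.05; mixing and
translation tied to the warp amplitude), random quadratic polynomial terms,
and a small TPS bump field anchored at 8 template landmarks, overall
amplitude 10 mm by default.  Digitization noise is isotropic Gaussian,
default σ = 2.0 mm, the magnitude of intra-observer landmark repeatability
reported for manual MRI landmarking.  The "sex effect" is one deterministic
mode (wider pelvis with a relatively shorter femur, applied with opposite
sign to alternating participants); `generic_proportions_bias` is a second
fixed mode (narrower inter-ischial spacing, shorter femur, longer tibia)
used to build generic-scaled stand-ins whose contrast with personalized
shapes appears as a single dominant PC.

Because the ground-truth family is representable by the fitted spline,
sub-millimeter recovery on noise-free participants tests the solver and the
plumbing, not the anatomical fidelity of TPS interpolation between sparse
landmarks on real bones.  What passing tests show: the operators are
mathematically correct, deterministic under seeds, and the pipeline
composes without leaking coordinate frames or units.  What they cannot
show: landmark identifiability on actual MRI, the adequacy of 106 landmarks
for real inter-individual variation, or simulation-level outcomes (joint
contact forces), which require motion data and a dynamics engine and are
outside this package's scope.

## Known limitations

- Hinge joints only; no patellofemoral mechanism (the patella is welded to
  the tibia, standing in for a rigid patellar tendon).
- One wrap cylinder per path segment; no sphere/ellipsoid obstacles and no
  multi-obstacle interaction.
- Muscle set reduced to 12 right-side muscles spanning hip, knee and ankle.
- The template's landmark positions are synthetic stand-ins; measured
  absolute dimensions describe the fixture, not any real population.
- `dshift`'s weight and the `pdrop` constants are conventions, configurable
  in `ObjectiveConfig`.
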