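# Methods

This note records the models, numerical choices and known limitations behind
`tmsfield`. It complements the README (which states the problem and the main
equations) and the module docstrings (which document interfaces).

## Head model

The head is a family of concentric spheres — scalp 85 mm, skull 80 mm,
CSF 75 mm, cortex 73 mm — of which the scalp and cortex are meshed
(icospheres; subdivision 4 → 2562 vertices, 5 → 10242). A smooth radial
displacement field (random real spherical harmonics of degree ≤ 3, rescaled so
its maximum absolute value equals the perturbation amplitude) is applied
independently to each meshed layer. The perturbation serves two purposes: it
makes surface normals deviate from the radial direction, so the
projection/ray/normal logic is exercised on non-trivial geometry, and it
spreads the scalp-to-cortex distance (SCD) across sites. With the default
amplitude of 1.5 mm the SCD realizes ≈ 12 ± 2 mm around the 12-mm nominal
gap; the clinical cohorts report 12.7–14.8 mm means. The nominal gap is fixed
by the layer radii, so the synthetic SCD is centered slightly below the
clinical values; this affects absolute field levels, not any of the contrasts
the package tests.

Tissue conductivities (0.465, 0.010, 1.654, 0.275 S/m for scalp, skull, CSF,
gray matter; 0.126 S/m white matter) are stored as metadata. For a
spherically symmetric conductor the induced E-field is provably independent
of the radial conductivity profile, so the field engine never reads them —
this is the key simplification that makes a desk-scale analytical surrogate
for FEM possible, and it is the reason a layered sphere loses nothing over a
homogeneous one.

## Field engine

The coil is discretized as magnetic dipoles normal to the coil plane; the
induced field inside the conductor uses the reciprocity/Sarvas closed form
(README). Numerical notes:

- Units are mm and A/μs at the interface, SI internally; fields are V/m
  before normalization and dimensionless after.
- The solution is linear in di/dt and exactly tangential; both properties are
  asserted in tests to machine precision, and the closed form is checked
  against an independent degree-40 spherical-harmonic Neumann solver
  (quadrature-fitted surface potential, finite-difference gradients) to
  < 1e-4 relative error on randomized configurations.
- Sample points must be strictly deeper than every dipole; violations raise a
  domain error rather than returning an unphysical value.

## Coil model

A generic 70-mm figure-8: wing radius 35 mm, wing centers 70 mm apart, 9
turns per wing, 16 dipoles per wing, opposed winding senses. No manufacturer
geometry is claimed; the turns count cancels under M1 normalization. Two
choices deserve explanation:

- **Wing axis.** Wing centers are separated along
  `cross(contact_normal, handle_dir)` — perpendicular to the handle, as in
  physical figure-8 coils, so the junction current runs parallel to the
  handle. On the sphere this makes the field decay slowly along the handle
  direction and quickly perpendicular to it; consequently a handle
  *perpendicular* to the LOI suppresses the anatomical target while a
  *parallel* handle spares it, which is the clinically observed pattern. The
  opposite convention (wings along the handle) inverts that prediction and is
  not used.
- **Dipole layout.** Each wing's dipoles lie on a point-symmetric layout
  (pairs at ±offset from the wing center, sunflower radii). A uniformly
  magnetized disc is equivalent to its boundary current loop, so this
  approximates the winding; the point symmetry makes the discretized field
  exactly odd under a 180° pose rotation, so the mirrored half of the
  orientation sweep (−180°…−30°) equals its partners to round-off, not to
  discretization error.
- **Lift-off.** The coil plane is tangent at the scalp contact point with a
  configurable standoff, default 0 mm (no coil-scalp gap is specified
  clinically).
- **Rotation sense.** "Counterclockwise" is the right-hand sense about the
  axis from the coil center toward the intracranial target. The viewpoint is
  a convention only: all sweep statistics are invariant to it because the
  sweep covers the half-turn and the field is 180°-periodic.

## Cohort generator

Each subject carries functional, anatomical and F3 cortical targets. The
anatomical center is the cortical projection of the synthetic-space analog of
(−38, 44, 26) (same direction, scaled to the cortical radius); the F3 center
is the cortical projection of the F3-analog scalp site in a 10–20-like frame
anchored at synthetic nasion/inion/vertex poles, with default arc fractions
chosen so it lands at the anatomical reference direction; the functional
center sits 22 mm posterolaterally along the cortical tangent plane.

Scatter is Gaussian and isotropic in the cortical tangent plane, then
re-projected to the surface: a **shared per-subject anatomy offset**
(σ = 2.90 mm/axis) moves all three targets together, and independent
residuals (functional 10.78, anatomical 3.03, F3 2.34 mm/axis) move them
apart. The shared component is essential: with purely independent jitter the
anatomical–F3 mean distance has a floor of ≈ 7 mm, above the measured
4.81 mm. The defaults were calibrated once, at n = 300, to the measured
cohort statistics and then frozen:

| statistic | calibration target | realized (n=300) |
|---|---|---|
| functional dispersion | 13.61 mm | ≈ 13.2–14.0 |
| anatomical dispersion | 5.17 mm | ≈ 5.2 |
| F3 dispersion | 4.59 mm | ≈ 4.6 |
| functional–anatomical mean distance | 24.45 mm | ≈ 23.7–24.1 |
| anatomical–F3 mean distance | 4.81 mm | ≈ 4.7–4.9 |

The functional–F3 distance is not independently controllable under this
covariance structure and realizes ≈ 24 mm versus the measured 21.40 mm; the
orderings (functional–anatomical > anatomical–F3, functional dispersion >
anatomical ≈ F3) are preserved. The measured covariance of the three targets
within subjects is not published, so the shared-plus-residual structure, and
the isotropic tangential form of the functional scatter, are modeling
assumptions.

All randomness flows from one cohort seed via `SeedSequence.spawn`, so
subject i is identical across cohort draws of any size with the same seed.

## Targeting and ROI metrics

- Nearest-surface projection returns the closest point on any face (Ericson's
  region classification over candidate faces from a vertex KD-tree), with
  ties broken toward the lowest face index. This is exact for the polyhedral
  surface; note the polyhedron itself sits up to one sagitta inside the ideal
  sphere (0.03 mm at subdivision 4).
- SCD casts the inward scalp-normal ray (Möller–Trumbore over all faces) and
  takes the first cortical intersection; if the ray misses, the distance to
  the nearest cortical point is used and logged. A dense ray-marching oracle
  confirms the ray-cast to 0.05 mm in tests.
- ROIs are Euclidean 10-mm balls of cortical vertices ("voxels" in the
  surface surrogate — no volumetric grid exists). The volume estimate is the
  members' surface-area share × an assumed 2.5 mm gray-matter thickness,
  ≈ 785 mm³ for a full 10-mm disc; the clinical volumetric ROIs are ≈ 1400
  mm³ because a sphere intersects more gray matter than one sheet. Only
  *comparability across equal-depth targets* is meaningful here, and that is
  what the tests assert.
- `E_⊥` averages the unsigned normal component by default (the sign
  convention for averaging is not specified clinically; signed averaging is
  available via a flag).

## What the synthetic testbed does and does not show

The sphere reproduces, with no tuning of the field engine: the dispersion
hierarchy and its ANOVA scale (F ≈ 36, η² ≈ 0.45 at n = 30 vs the reported
37.60 / 0.46); the equal-depth null result (E_ROI under the coil within ~2 %
across the three targeting methods); functional > anatomical field with the
coil over the functional target; and the orientation selectivity pattern
(perpendicular-to-LOI handle suppresses the anatomical target, parallel
spares it, with the functional target essentially orientation-invariant).

It does not reproduce: absolute E_ROI levels (normalization geometry differs
from real heads); the E_⊥ magnitudes — in a concentric sphere the total field
is tangential, so the normal component at the cortex is near zero and only
the mesh perturbation contributes, whereas real sulcal walls receive large
normal components; and the exact ratio magnitudes (the smooth sphere gives
stronger perpendicular suppression, ratio ≈ 2.9 vs the measured 1.69).
Patient-level values require the original MRIs and FEM and are treated as
published inputs, not reproduction targets.

## Problem sizes and determinism

Default study conditions: 30 subjects, cortex/scalp meshes at subdivision 5
(10242 vertices), 10-mm ROIs (≈ 47 vertices), 32 coil dipoles, 6 explicit
sweep angles plus initial/parallel/perpendicular poses. A full fit runs in a
few seconds on one CPU; generator calibration checks use n = 300. Every run
is deterministic given its config and seed, and the report bundle
(cohort/pose/metric CSVs, histogram and stats JSON, summary text, config
echo) is byte-stable across repeated runs.
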