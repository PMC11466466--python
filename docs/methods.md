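# Methods

This note documents the models implemented in `adaptcheck`, the parameter
choices that matter, what the synthetic phantom does and does not emulate,
and the numerical decisions a maintainer would want written down.

## Geometry and conventions

Physical coordinates are LPS millimetres (the DICOM patient convention);
voxel indices are 0-based and grid positions refer to voxel centers. Every
spatial transform in the package — rigid, B-spline displacement field, or a
composition — is a *pull* map: it takes a fixed-image physical point to the
corresponding moving-image physical point, and resampling evaluates the
moving image there. Rigid transforms are six-parameter (rotations about
x, y, z composed as Rz·Ry·Rx about a center, then translation), matching
ITK's Euler3D transform with ZYX composition. Deformation fields are
uniform cubic B-spline free-form deformations: displacement is the
tensor-product spline of per-node mm coefficients, so zero coefficients give
the exact identity and the dense field is C²-smooth by construction.

Interpolation defaults: linear for intensities, nearest (or linear +
0.5 threshold, ties inside) for labels and masks; outside-volume fill is
−1000 HU for CT-like images and 0 for dose and masks.

## Rigid stage

Prealignment follows the clinical convention that the planned isocenter
coincides with the CBCT scan center: when the plan provides an isocenter,
the initial transform is the pure translation `−isocenter`; without one,
the grids' geometric centers are aligned. Refinement runs on SimpleITK's
registration framework (dense Mattes mutual information by default,
regular-step gradient descent, 3-level shrink pyramid). Two non-obvious
choices:

* the optimization runs with the CBCT as the *fixed* image (masked to its
  field of view) and the planning CT as moving, then inverts the result.
  With the roles the other way round most metric samples map outside the
  small CBCT volume and the optimizer can "improve" the metric by pushing
  samples off the image;
* the refined transform is only returned if it actually improves the
  metric over the initialization; otherwise the initialization is kept.

On ten seeded phantoms with offsets up to ±5 mm/axis and ±2°/axis the
median recovery error is ≈ 0.2 mm and ≈ 0.06° (the test suite asserts
< 1 mm and < 0.5°).

## Deformable engine

One free-form-deformation optimizer serves both intensity registration and
the structure-guided ROI registration. The objective is the mean squared
difference summed over one or more channel pairs (each normalized by the
standard deviation of its fixed channel), plus a bending-energy penalty
approximated by the mean squared second difference of the control
coefficients. Minimization is L-BFGS-B over the control displacements with
analytic gradients, on a two-level image pyramid (working resolutions 4×
and 2× the voxel spacing — the 25 mm control spacing cannot represent
finer detail anyway). Numerical choices that proved essential:

* **Smooth sampling.** Moving channels and their spatial gradients are
  sampled with cubic spline interpolation and nearest-edge extension.
  Linear interpolation has gradient kinks exactly on the voxel lattice —
  where all working points start — and a constant-fill boundary introduces
  a cliff at zero displacement; both break the Wolfe line search.
* **Objective preconditioning.** The objective is rescaled so the starting
  gradient has unit infinity-norm; without this the first quasi-Newton
  steps are orders of magnitude below the millimetre scale and the
  relative-reduction stop fires immediately.
* **Relative bending weight.** The penalty weight is
  `smoothness_weight × (metric value at the start of the level)`, making
  the default (0.05) scale-free across intensity units and channel counts.
* **Bounded coefficients.** Coefficients are box-bounded at 0.4× the
  control spacing — the classical sufficient condition against folding,
  which also stops the coarse level from chasing aliased matches.
* **Soft-tissue window.** Intensity registration clips both images to
  [−150, 250] HU first. Bone/air edges otherwise dominate the SSD a
  hundredfold and drown the organ signal that target propagation needs.
* If the optimized field still folds (non-positive Jacobian), the
  registration is retried once with tenfold smoothness.

### Structure-guided ROI registration

The nine ROIs are collapsed into one label image (air 0, skin 1, femoral
heads 2/3, pelvis 4, spinal cord 5, rectum 6, small intestine 7, bladder 8;
overlaps resolve to the highest = most target-important label, voxels
outside the skin are air). Labels are not registered on their raw integer
values — arithmetic on labels is meaningless. Each label present on both
sides contributes a signed Euclidean distance map clamped to ±20 mm
(negative inside), and the multi-channel SSD is minimized with the shared
engine at 25 mm control spacing. Working points are restricted to the
±8 mm band around structure boundaries: beyond it the clamped maps are
constant plateaus with zero gradient, so the restriction is purely a
speedup. The registration runs fixed = fraction-day labels, moving =
planning labels, so the resulting pull field directly propagates planning
CTV/PTV onto the fraction anatomy; PTV ⊇ CTV is repaired by union if a
warp violates it. Because only masks enter the objective, the result is
bitwise independent of CBCT image quality.

## Synthetic CT and combined CT

The learned CBCT-to-CT translation used clinically is replaced by a
deterministic two-stage calibration fitted against the rigidly aligned
planning CT inside the FOV (any callable with the same signature can be
plugged in instead):

1. **Radial shading correction.** CBCT shading (global shift + cupping) is
   estimated as the per-annulus median of the CT-vs-CBCT residual, clipped
   to ±120 HU (anatomy mismatch at bone/air edges produces huge dipoles
   that would otherwise leak in), interpolated along the in-plane radius
   about the scanner axis, and subtracted.
2. **Monotone intensity map.** Voxel pairs are binned into 16 knots over
   [−1000, 1500] HU by CBCT value; each knot is the (median CBCT,
   median CT) of its bin, pool-adjacent-violators-corrected so the map
   never reorders two HU values, linear between knots, extended with the
   end-segment slopes. A near-uniform input (fewer than two populated
   bins) falls back to a pure median shift.

The combined CT lives on the planning-CT grid: voxels whose rigidly mapped
point lies deeper than 5 mm inside the CBCT FOV take exactly the calibrated
CBCT value, voxels outside the FOV take exactly the planning CT value, and
a cosine ramp blends the 5 mm seam (avoiding dose-gradient artifacts
there). Calibration happens before splicing. The deformed planning CT
(dose-calculation image) is the planning CT pull-warped by the intensity
registration field onto that grid.

## Dose engine

The engine recomputes the plan's full-course dose deterministically; it is
a primary-photon model, not a transport calculation. Per beam: source at
SAD (1000 mm) from the isocenter along the gantry direction; each voxel
receives

    weight × penumbra × exp(−(μ/ρ) · radiological depth) × (SAD / r)²

with μ/ρ = 0.05 cm²/g (≈ 6 MV effective), the radiological depth the
density line integral from the source (density from a piecewise-linear HU
table anchored at air → 0, water → 1.0, 1000 HU → 1.6, 3000 HU → 2.9),
and an error-function penumbra of σ = 3 mm in beam's-eye-view coordinates
at the isocenter plane (physically scaled by divergence). Depth along each
ray is a midpoint-rule integral at ≈ 1 mm steps with the grid entry point
located exactly, which makes the integral *exact* in uniform media; the
single-ray `radiological_depth` API uses exact Siddon voxel traversal. The
plan dose is normalized so the mean over a 1 cm sphere at the isocenter
equals the prescription, then scaled by the plan's output factor
(`norm_factor`, the meterset analogue). Phantom plans set that factor so
PTV D₉₇% equals the prescription — the clinical normalization that makes
the original plan satisfy its own coverage constraints with margin. All
doses are full-course Gy (45 Gy prescription scale), matching how the
clinical thresholds are expressed. Dose numbers are internally consistent
— anatomy changes move DVH metrics in physically sensible directions — but
are not comparable to a Monte Carlo or clinical TPS calculation.

## Evaluation

* **Dice**: 2|A∩B|/(|A|+|B|); two empty masks are defined as 1.0 (logged).
* **DVH**: cumulative, 0.01 Gy bins. D_i is the largest dose whose
  cumulative volume is ≥ i %, linearly interpolated across the crossing
  bin (one-bin accuracy against direct voxel sorting); V_d interpolates
  the curve at d; V₁₀₀% evaluates at the attached prescription.
* **Gamma**: global 3D, normalization = max of the reference dose,
  low-dose threshold applied to reference voxels. The evaluated dose is
  trilinearly interpolated on a DTA/10 offset lattice scanned in order of
  increasing distance with per-voxel early exit; offsets beyond one DTA
  cannot rescue a voxel (their distance term alone exceeds 1), so the scan
  is exhaustive for pass/fail. The suite verifies per-voxel agreement with
  a no-shortcut 3×DTA-ball scan.
* **Decision**: `adapt` if any target constraint fails (CTV V₁₀₀% < 99 %,
  PTV V₁₀₀% < 95 %, CTV D₉₉% or PTV D₉₅% below prescription; boundary
  values pass); `review` if any OAR volume metric rose more than 5
  percentage points over the original plan (a configurable policy margin —
  the clinical sources fix only the target rules); else `no_adaptation`.

## The phantom and what passing tests mean

The generator builds a pelvis-like anatomy at 96³ × 2.5 mm: an elliptical
body with a fat shell, a pelvic ring open anteriorly with a spinal canal,
femoral heads, bone marrow as the eroded bone interior, bladder, rectum,
small intestine, a cervix-like CTV between bladder and rectum (75 HU,
visibly denser than surrounding soft tissue, as contrast-enhanced cervical
anatomy is) and PTV = CTV + 7 mm. Organ sizes and positions jitter ±5 %
per case. The plan is a four-field box fitted to the PTV, 45 Gy in 25
fractions. Fraction-day anatomy applies a known smooth deformation — a
random B-spline field normalized to 8 mm maximum dense displacement on a
20 mm control lattice, plus an exact local volume-scaling component
realizing the bladder volume factor (default 1.3), plus an optional bulk
target shift for decision-dichotomy scenarios — followed by a known rigid
setup offset (±5 mm, ±2° per axis). Fields are rejected and re-damped
until the Jacobian determinant stays above 0.05 (no folding). The CBCT is
the warped CT cropped to a cylindrical FOV (0.7× the smaller body
semi-axis, 70 % of the axial extent), with +30 HU shift, 80 HU
center-to-edge cupping and σ = 20 HU Gaussian noise; outside the FOV is
exactly −1000 HU. One RNG stream per case, keyed by the seed, with
sub-stages drawing in fixed order: generation is bit-reproducible.

Because fraction-day structures are produced by the *same* propagation
operator used for scoring, ground-truth consistency is exact by
construction, and every accuracy number (rigid recovery, propagation Dice,
decision dichotomy) has a known reference. What the phantom does *not*
emulate: real CT texture and scatter physics, non-radial CBCT artifacts,
sliding organ interfaces, intra-fraction motion, and realistic
low-contrast segmentation difficulty (fraction-day organ masks are exact
by construction, standing in for a learned segmenter or manual contours).
Passing tests therefore demonstrate that the machinery is correct and
self-consistent under controlled conditions — not that clinical accuracy
figures transfer.

The registration-route comparison (rigid vs. intensity-deformable vs.
ROI-guided propagation of the targets) runs on clean paired-CT phantom
cohorts — the setting in which such comparisons are made on repeat-CT
clinical data — and reproduces the expected ordering: ROI-guided best,
intensity DIR intermediate, rigid worst, with ROI exceeding rigid by well
over 0.03 mean CTV Dice.

## Problem sizes and determinism

Default validation sizes: 96³ phantom voxels, ten-case cohorts for
registration statistics, 8–12³ dose grids for gamma-oracle checks; the
full eight-stage pipeline runs in about 1.5 minutes per fraction on one
CPU. Everything is deterministic given the seed: registrations use dense
metrics and deterministic optimizers, the generator uses one seeded RNG,
and re-running a configuration reproduces artifacts bit for bit.

## Known limitations

* The dose engine ignores scatter, electron transport and MLC sequences;
  absolute dose accuracy is not a goal, only sensitivity to anatomy.
* The intensity-deformable metric is SSD on HU-calibrated images; a true
  multi-modal metric (mutual information) is available only on the rigid
  path, where raw CBCT is encountered.
* The combined CT shows undeformed planning anatomy outside the CBCT FOV,
  so the deformable field is biased toward identity near the FOV seam; the
  targets sit well inside the FOV where this does not matter.
* Fraction-day influencer masks are an input, not a product: the package
  deliberately does not segment images.
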