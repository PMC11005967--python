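# Methods

This note documents the models behind `overlapdose`: what the synthetic
geometry and dose generators emulate, how their parameters were chosen, the
numerical conventions, and what conclusions the synthetic study does and
does not support.

## Predictive parameters

For an OAR of volume `V_OAR` overlapping a target of volume `V_PTV` by
`V_OV` (all in cc):

* `COPP = V_OV / V_OAR` — the classical overlap ratio used to predict
  achievable OAR sparing before optimization.
* `POPP = COPP * (V_PTV / V_OAR)` — the volume-corrected variant, built on
  the assumption that the achievable OAR dose rises with target size and
  falls with OAR size.

Both are exact arithmetic identities of the three volumes; the package
computes them either from voxel masks or directly from known volumes.

## Phantom geometry

The phantom is an analytic surrogate for a benchmark prostate structure
set: the true benchmark contours are not published as equations, so the
package uses primitives whose every calibration target is solvable and
oracle-checkable.

* **PTV**: axis-aligned ellipsoid at the origin, semiaxis ratio
  (1.2, 1.2, 1.0) in (LR, AP, SI); the scale is solved by bisection on the
  voxelized volume so the achieved volume hits 162.7 cc (or 188.0 cc for
  the large-target arm, which grows only in LR/AP at fixed SI extent — the
  cranio-caudal extent of a prostate target changes little as the target
  grows laterally).
* **Rectum**: SI-oriented cylinder posterior to the PTV. Raw radius
  7.81 mm and length 97 mm follow *analytically* from the three published
  expanded volumes (42.5/50.0/58.2 cc at +4/+5/+6 mm LR/AP margin): the
  three (margin, volume) pairs over-determine (r0, L) and agree to <1%,
  which is strong evidence the underlying structure is indeed a cylinder
  expanded in-plane.
* **Bladder**: ellipsoid anterior–superior to the PTV, raw semiaxes
  (26, 24, 22) mm, which reproduce the published uniformly expanded volumes
  (124.2/165.0/197.0 cc at +7/+10/+12 mm) to within 1.5%.
* **Positions** (rectum centre y = −26 mm, bladder centre (0, 35, 26) mm)
  were calibrated once so the 81-case cohort reproduces the published
  cohort statistics — rectum volume 50.4 ± 6.7 cc, bladder 160.9 ± 28.9 cc,
  rectum overlap ratio 0.103 ± 0.028, bladder 0.089 ± 0.021 — and then
  frozen.

Margins in the case generators are applied to the *analytic primitive*
(cylinder radius + e; ellipsoid semiaxes + e) rather than by dilating the
voxelized mask: voxel-centre dilation of a thin structure under-reaches the
true offset surface by up to one voxel, which at 2 mm spacing would miss
the published volume targets. The general-purpose `expand_mask` operator
(Euclidean distance transform in margin-scaled coordinates, supporting
per-axis and per-sense margins) remains available for masks of arbitrary
origin and is validated against analytic offset volumes at 1 mm spacing.
Anterior/posterior shifts are applied to the primitive centre before
rasterization, which keeps the 5/8/11 mm shift levels distinct on a 2 mm
grid (a whole-voxel mask shift would alias 5 → 4 and 11 → 12 mm);
expansion and translation commute, so the order of operations is
immaterial.

**Overlap targets** (rectum overlap 3.3/5.3/7.7 cc, bladder overlap
13.2 cc in the six-case family) are solved by bisection on the structure's
AP centre coordinate with re-rasterization at each trial position. A
whole-voxel mask-shift solver is also provided, but one 2 mm voxel layer
changes the rectum–PTV overlap by 0.5–1 cc, so only the continuous-centre
path can honour the 0.15 cc tolerance; re-rasterization moves the achieved
overlap in steps of individual surface voxels (~0.01–0.05 cc).

Grid default: 2 mm isotropic over a 90 × 180 × 130 mm extent (263k voxels),
a typical dose-grid resolution; 1 mm is used in convergence tests. Voxel
occupancy uses the voxel-centre rule with no partial-volume weighting, so
one voxel (0.008 cc at 2 mm) is the quantum of every volume; stated
tolerances (0.15 cc for solved overlaps, 3–5% for structure volumes) absorb
this quantization.

## Dose emulator

The emulator is a stand-in for a commercial inverse-optimized planning
system. It does not model beams, arcs, MLCs or 6-MV transport; it models
the three properties of an optimized conformal plan that overlap-based
prediction depends on:

```
D(v) = Rx * [ b + (1−b) * logistic((m − d(v)) / σ_eff) ] * S(v) * (1 + ε(v))
```

* `d(v)` — signed Euclidean distance to the PTV surface (negative inside),
  from two complementary distance transforms with physical spacing.
* `σ_eff = σ * (V_PTV / 162.7 cc)^(1/3)` — penumbra scale. The cube-root
  factor makes the falloff track the target's linear size: larger targets
  need larger fields, whose scatter and penumbra widen the dose bath. This
  is what lets two geometries with equal overlap ratio but different PTV
  volumes receive different OAR doses — the effect the volume-corrected
  parameter is designed to capture. The exponent is fixed at 1/3 on
  dimensional grounds.
* `m` (edge margin, default 1.5σ) — places the logistic midpoint *outside*
  the target, the way the prescription isodose of a real plan wraps the PTV
  with a small margin. With the midpoint exactly on the surface,
  near-surface target voxels would sit at ~60% of the prescription, and
  global renormalization to 95% coverage would push the maximum dose far
  beyond any clinically plausible ceiling (we cap at 1.25 × Rx).
* `S(v)` — optimizer-feedback sparing. Inside each OAR,
  `S = 1 − γ (V_OAR / V_ref) * logistic(d/σ_eff)` with γ = 0.12 and
  reference volumes 50 cc (rectum) / 165 cc (bladder); the logistic ramp
  feathers the term to zero inside the target so coverage is never traded
  away. This emulates the inverse optimizer pushing dose off an organ in
  proportion to how much of it sits in the objective function. Without it,
  dose would be a pure function of distance to the target, intermediate-dose
  volumes would carry no organ-size information, and no volume-corrected
  parameter could outperform the plain overlap ratio — contrary to what
  optimized plans show. With γ = 0 the model reduces to the pure falloff
  and the dose is a monotone non-increasing function of the signed
  distance (a property the tests pin); with γ > 0 monotonicity holds
  outside the OARs.
* `ε(v)` — zero-mean multiplicative noise, Gaussian-filtered white noise
  normalized to unit variance, amplitude 2%, correlation length 15 mm,
  seeded per plan. Smooth fields mimic plan-to-plan optimizer variability
  without voxel-level speckle.
* Finally the field is scaled by the smallest factor ≥ 1 such that 95% of
  PTV voxels receive ≥ 75.6 Gy (exact order statistic); a plan needing a
  maximum dose above 1.25 × Rx raises a plan-failure error instead of
  silently under-covering.

**Presets.** IMRT σ = 8.2 mm, VMAT σ = 7.0 mm (margin 1.5σ, background
b = 0.18, γ = 0.12 for both). σ was calibrated per modality so the 81-case
cohort's rectum mean dose lands in the published bands (45.4 vs 44.7 ± 1.6
Gy for fixed-field; 41.9 vs 41.4 ± 1.8 Gy for arcs); the σ ordering encodes
the observed modality contrast (fixed-field delivery leaves more
intermediate dose than arcs). All parameters are configuration, not
hard-coded.

## Metrics and statistics

* `V_xGy` uses the closed bound (dose ≥ x) and is reported as percent of
  structure volume; "receiving the prescription dose" and "receiving more
  than the prescription dose" are harmonized to ≥ Rx (both switchable).
  With a 1-Gy sweep and 2% noise the open/closed choice is immaterial.
* `D_p` comes from exact order statistics (the smallest dose d with
  V(d) ≥ p), never from interpolated histogram bins, so the homogeneity
  index has no bin-width sensitivity. The DVH object retains voxel doses;
  its 0.1 Gy binning is display-only.
* Conformity number `CN = (TV_PIV/TV)(TV_PIV/PIV)`; `PIV = 0` is reported
  as CN = 0 with a warning rather than an error.
* The correlation sweep computes Pearson R of V_xGy against each parameter
  at every 1-Gy level from 20 to 75 Gy. Comparing the two correlations at
  a level is a *dependent overlapping* correlation problem (both share
  V_xGy, and the predictors are strongly inter-correlated), so the default
  test is Williams' t (Steiger's formulation) with n − 3 degrees of
  freedom, whose empirical size at n = 81 is ~0.05 in simulation. A
  windowed paired t-test over neighbouring levels is provided as an
  alternative reading of "paired-samples t-test applied to correlation
  series"; both p-value columns are written side by side, uncorrected per
  level (matching per-level 5% reporting) with a Holm-corrected copy for
  transparency.
* The threshold dose `Dth` is the linear interpolation of
  `Δr = r_POPP − r_COPP` at its first positive-to-negative sign change
  scanning upward in dose; absence of a crossing is a valid outcome and
  multiple crossings are logged as a warning, with the first reported.
  The statistics run on all 81 plans by default; goal-failing plans are
  flagged, not excluded (a goals-only mode exists).

## What the synthetic study shows — and does not

With default presets and seeds, the replica reproduces the qualitative
finding: the plain overlap ratio predicts the high-dose volumes better
(r ≈ 0.99 for rectum V70Gy), the volume-corrected parameter predicts
intermediate-dose volumes better (e.g. rectum V37.5Gy r = 0.92 vs 0.81 for
fixed-field plans), and the crossing sits at an intermediate threshold
(67 Gy fixed-field, 63 Gy arcs, for the rectum). Because the emulator's
sparing term *builds in* a first-order version of the optimizer behaviour
the parameters exploit, these runs validate the pipeline and the direction
and rough location of the effects — they are not independent evidence about
clinical plans.

Known divergences from a commercial optimizer, reported as computed and
left uncorrected: the homogeneity index is pessimistic (~0.17 vs 0.065–0.09;
the emulator has no intra-target flattening), bladder mean dose runs ~5 Gy
high and its threshold dose correspondingly high, rectum V37.5Gy runs ~10
percentage points low, and more plans pass the dose goals (69–70 of 81 vs
58–63) because emulated doses lack the optimizer's occasional hard
failures. The phantom also omits femoral heads, deformable anatomy and
inter-fraction motion, and real contours are not ellipsoids and cylinders —
conclusions about clinical data require clinical plans, which the DICOM-RT
reader accepts.

## Numerical conventions

* Coordinates: +x left, +y anterior, +z superior; millimetres; volumes cc.
* Whole-voxel mask translation (round-to-nearest) preserves volume exactly
  and raises on clipping rather than truncating.
* Bisection solvers treat voxelized measures as monotone step functions:
  the bracket collapses below voxel pitch and the endpoint closest to the
  target is returned, with an explicit error if the tolerance cannot be
  met.
* Per-case noise seeds derive deterministically from the experiment seed
  and case index, so cohorts are reproducible byte-for-byte and
  independent of evaluation order.
* Degenerate inputs fail loudly: empty masks for expansion/distance/DVH,
  constant predictors in regression, overlap targets outside the attainable
  range, structures pushed off the grid.
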