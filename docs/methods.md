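# Methods

This note documents the models, estimators and numerical choices behind
`depotmetry`, what the synthetic phantoms do and do not emulate, and the
known limitations.

## Coordinate and unit conventions

Volumes are 3D grids in `(depth, slow-lateral, fast-lateral)` axis order —
a stack of cross-sectional B-scans — with voxel spacing in µm, voxel
centres at `(i + 0.5)·spacing`, and 0-based indices. Deposit volumes are
reported in µl (1 µl = 1 mm³ = 10⁹ µm³) and surface areas in mm²; the
conversion constants live in `depotmetry.io` only. OCT measures optical
path length along depth, so an opt-in correction divides the depth
spacing by a tissue group refractive index (`apply_refractive_correction`);
the index actually applicable to a given instrument/tissue combination is
configuration, not a package default, and the applied value is recorded in
the output metadata.

## Segmentation

Deposits scatter far less than dermis and appear as dark compact regions
in a bright speckled background. The segmenter is a classical two-stage
intensity pipeline:

1. **Detection.** Gaussian smoothing at `detect_sigma_um` (default
   150 µm, converted per axis to voxels) suppresses speckle until the
   histogram is bimodal; Otsu's threshold then isolates the dark class.
   A contrast guard rejects volumes where the "dark" class is not
   actually dark (mean(dark)/mean(bright) > 0.5): on a deposit-free
   volume Otsu merely splits the speckle mode in half, and the guard
   converts that into an empty mask rather than a phantom detection.
2. **Boundary refinement.** Heavy smoothing biases the detected boundary
   by roughly the smoothing scale. The deposit and background plateau
   levels are therefore re-estimated away from the boundary halo (eroded
   interior / dilated exterior, halo radius 2·`detect_sigma_um`), and the
   final mask is the lightly smoothed volume (`refine_sigma_um`, default
   60 µm) thresholded at the midpoint of the two levels. A step edge
   between two plateaus crosses its midpoint at the true interface
   independent of smoothing scale, which restores sub-voxel boundary
   accuracy.
3. **Cleanup.** Morphological closing then opening with an ellipsoidal
   structuring element of physical radius `morph_radius_um` (default
   120 µm), followed by largest-26-connected-component selection.
4. **Minimum-volume floor.** Candidates below `min_volume_ul` (default
   0.5 µl) are discarded and an *empty* mask is returned — deposits of
   interest are tens of µl, so sub-µl candidates are speckle artifacts.
   An empty mask is a result, not an error; the pipeline logs it.

All kernel sizes are specified in µm and converted per axis, so moderate
anisotropy is handled transparently; a spacing anisotropy beyond 20:1
degenerates the structuring elements and raises an error advising
resampling. Size ties in component selection break toward the component
containing the lexicographically smallest voxel, making the output fully
deterministic.

Operator corrections enter through `merge_manual_correction` with
`replace`, `union` or `intersection` semantics and provenance recorded in
the mask metadata, or by supplying a corrected mask file directly in the
pipeline configuration.

## Morphometry

Volume is voxel count × voxel volume. Surface area — the delicate
quantity on a voxel grid — has three estimators:

* **`naive_faces`** sums exposed voxel-face areas (per-axis face areas,
  so anisotropy-aware). It measures the staircase, not the underlying
  smooth surface: the expected overestimate for an isotropically oriented
  surface patch is the mean of |n_x|+|n_y|+|n_z| over the sphere, i.e.
  3/2. It is kept as a documented baseline and excluded from sphericity
  guarantees.
* **`weighted_config`** (default) counts the local 2×2×2 voxel
  configurations along the boundary and sums per-configuration weights.
  Weights depend on the foreground count (1–7) with the complement
  symmetry w(c) = w(8−c) enforced, and were calibrated once by
  non-negative least squares so that digitized spheres of radii 5–50
  voxels reproduce 4πr² (`scripts/calibrate_surface_weights.py`; the
  frozen constants are in `depotmetry.morphometry`). Calibration residual
  is < 2% over the calibrated radius range (worst at the smallest radii),
  −0.3% at r = 40.
* **`isosurface_mesh`** triangulates the implicit surface by marching
  cubes with physical spacing and sums triangle areas. It serves as the
  independent oracle for `weighted_config` in the tests.

The implicit surface shared by the calibrated estimators is the 0.5 level
set of the occupancy indicator after mild Gaussian smoothing
(σ = 1.2 × finest spacing). Smoothing displaces a curved boundary by
O(σ²κ) — negligible for deposits tens of voxels across — and removes the
staircase that otherwise corrupts mesh areas by ~9% on spheres.
Anisotropic grids are handled by `isosurface_mesh` natively and by
`weighted_config` through tri-linear resampling of the smoothed field to
an isotropic grid at the finest spacing, re-thresholded at 0.5. Masks are
padded with background first, so faces at the grid border count as
boundary.

Sphericity is S = π^{1/3}(6V)^{2/3}/A with V in mm³ and A in mm²;
S = 1 exactly iff A is the area of the sphere of volume V. Closed-form
anchors used in the tests: cube (π/6)^{1/3} ≈ 0.8060; 2:1 prolate
spheroid ≈ 0.9287. Because a sphere maximizes S, any overshoot above 1
for a digitized sphere is pure surface-digitization error (≲0.5% with the
calibrated estimators); `measure()` clips S at the physical bound of 1
for the calibrated estimators, while `compute_sphericity` always returns
the raw formula value. An empty mask yields an explicit no-deposit result
(V = 0, A and S NaN), never silent zeros.

Scale behaviour is the practical sanity check: multiplying all spacings
by k scales V by k³ and A by k² exactly, and re-digitizing the same
physical shape at half the spacing changes S by < 2%.

## Volume kinetics

Deposits swell for some weeks after injection and then degrade. Per
deposit the package reports the observed peak (earliest timepoint wins
ties), V_increase = V_max − V0, V_max_rel = 100·V_max/V0 (computed per
deposit, then averaged: a mean of ratios, which can legitimately differ
from the ratio of group means), and a half-life from the post-peak fit

    V(t) = V̂_max · exp(−λ·(t − T_max)),   T_1/2 = ln 2 / λ.

The fit is ordinary least squares on log-volumes over t ≥ T_max —
deterministic and closed-form, adequate at the few-percent measurement
noise of volumetric imaging; a Levenberg–Marquardt refinement on the
volume scale is available (`method="nonlinear"`). By default the peak
amplitude is a free intercept in log space (the statistically standard
reading of "an exponential fit starting at the maximum volume");
`fix_peak=True` anchors the curve exactly at the observed peak. Either
way the *observed* V_max is what enters the summary tables.

Degenerate cases are explicit: λ ≤ 10⁻¹² (a numerical zero — a perfectly
flat tail fits a slope of ~10⁻¹⁷) marks the result *censored* with an
infinite half-life, never a negative one; a series whose maximum is its
final point never began to decay and is likewise censored; an interior
peak with fewer than three post-peak points raises an underdetermined-fit
error. Group summaries exclude censored half-lifes and report their
count; SD is the sample SD, with SD = 0 for singletons by convention.
Consequences of the fit's construction, verified in tests: shifting all
times by a constant or scaling all volumes leaves λ and T_1/2 unchanged,
and noiseless exponentials are recovered to machine precision.

## Group statistics

One-way ANOVA (scipy) followed by Tukey's HSD on the studentized-range
distribution; unequal group sizes use the Tukey–Kramer harmonic-mean
adjustment (scipy's `tukey_hsd`). Significance threshold 0.05,
configurable. All-identical input is answered with F = 0 and p = 1
rather than 0/0. No additional correction is applied across *parameters*
(volume, sphericity, half-life are tested independently) — a deliberate
caveat, matching common practice for this kind of longitudinal panel.
The ANOVA p-value is validated against a 10⁵-permutation oracle of the F
statistic on a small fixed table; the residual discrepancy beyond
Monte-Carlo error reflects the normal-theory vs permutation reference at
n = 5 per group and is bounded at 0.02 in the test.

## Synthetic phantoms and cohorts

The phantom generator provides the ground truth the in-vivo data cannot:
an exact deposit mask underneath a realistic-looking volume.

* **Geometry.** The default test grid is 64×128×128 voxels at
  (50, 78.125, 78.125) µm — a downscaled version of the instrument's
  512×1500×1536 voxels over a 10 mm × 10 mm lateral field, chosen so the
  full suite runs in seconds. The instrument's axial physical extent is
  not tied to a published length, so depth spacing is a free parameter
  (default covers 3.2 mm of tissue). The full-resolution geometry runs
  through the same code path.
* **Deposit shapes.** A flat ellipsoid (default semi-axes 500×2500×2500
  µm, ≈13 µl — the low-viscosity commercial filler morphology) or a
  nodular union of overlapping spherical lobes (default 5 lobes of radius
  800 µm scattered within 600 µm, ≈5 µl — the higher-viscosity test-gel
  morphology). Lobe centres are drawn with the seeded generator; the
  union must be a single 26-connected component (guaranteed when the
  scatter radius is below the lobe radius, re-drawn then errored
  otherwise). Deposits must lie strictly inside the grid.
* **Intensities.** Background mean 0.45, deposit mean 0.05 (deposits are
  nearly non-scattering but show minor internal reflectors), multiplied
  by i.i.d. gamma speckle with unit mean. The default speckle contrast of
  1.0 is the fully developed limit (exponential intensity statistics) —
  first-order speckle behaviour, which is what threshold-based
  segmentation is sensitive to.
* **Not emulated:** depth-dependent attenuation and shadowing, confocal
  gating, refraction at the skin surface, skin-layer anatomy
  (epidermis/dermis/panniculus), vessels, motion. Passing the phantom
  suite therefore demonstrates correct recovery under speckle and
  anisotropy — the dominant difficulties for dark-deposit volumetry — but
  not robustness to layered-tissue confounders; on real data the
  manual-correction path exists precisely for such failures.

Longitudinal series follow v(t) = v0·(1 + s·t/t_max) up to the peak and
v0·(1+s)·exp(−λ(t−t_max)) after it, with multiplicative lognormal noise
of unit mean and CV `noise_cv` (default 0.05). Only the post-peak
exponential is constrained by the half-life analysis; the linear pre-peak
ramp is a simulator choice. The default measurement schedule is the
study-style 0, 2, 4, 6, 8, 10, 12, 16, 20, 24 weeks.

Cohort simulation mirrors the in-vivo study conditions: 22 mice, three
substances per mouse at randomized dorsal sites, group parameters
(baseline volume ≈18–21 µl with 4–6 µl SD, swelling 75–95%, peaks at
3.3–5 weeks, half-lifes 21.4–31.5 weeks) with lognormal between-deposit
half-life spread (CV 0.5) and truncated-normal baseline volume and
swelling — variability magnitudes chosen to match the reported
between-animal SDs. The cohort recovery test runs this at the full 22
mice through the pipeline's table path; the imaging stages are exercised
end-to-end separately (a single deposit imaged at five timepoints,
segmented, measured and fitted, recovering its generating half-life
within 10%), because running all ~660 cohort volumes through segmentation
would dominate the suite's runtime without changing what is tested —
half-life and relative-volume estimates are invariant to the small
(<5%) volume-scale errors segmentation can introduce.

## Numerical choices, in one place

* Surface weights frozen from a one-time sphere calibration (above);
  implicit-surface smoothing σ = 1.2 × finest spacing.
* Sphericity clipped at 1 in `measure()` for calibrated estimators.
* Segmentation: detect σ 150 µm, refine σ 60 µm, morphology radius
  120 µm, floor 0.5 µl, contrast-ratio guard 0.5, anisotropy limit 20.
* Kinetics: λ censoring threshold 10⁻¹²/week; earliest-tie peak;
  log-linear default, nonlinear optional.
* SD convention: sample SD (ddof = 1), 0 for singletons.
* Report CSVs are written with a fixed float format (`%.10g`) so reruns
  are byte-identical.

## Limitations

* The segmenter is a classical stand-in with the same contract as a
  learned segmenter (a mask an operator may correct); it assumes a single
  dark deposit and will return the largest dark structure if several are
  present.
* Localization is reported as centroid depth only; no classification of
  deposits above/below the subcutaneous muscle layer.
* No mechanistic swelling model: the pre-peak ramp is phenomenological,
  and the half-life is a descriptive, not mechanistic, parameter.
* The rapid-degradation exclusion applied to control substances in animal
  studies is not automated — no principled threshold exists; censoring
  plus the logged skip reasons make such deposits visible instead.
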