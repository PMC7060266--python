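# depotmetry

Longitudinal volumetric analysis of intradermal hydrogel deposits in 3D
OCT-like volumes.

Injected hyaluronic-acid fillers form discrete, low-scattering deposits in
the skin that swell during the first weeks after injection (water uptake)
and are then degraded over months. Dermatologic OCT images them as dark,
compact regions inside a bright speckled dermis, which makes their volume,
shape and longevity quantifiable *in vivo*. `depotmetry` implements the
full analysis chain for such data, aimed at preclinical imaging groups who
need reproducible deposit volumetry without hand-measuring B-scans:

1. **Segmentation** — a classical intensity-based segmenter (smoothing →
   Otsu dark-class detection → boundary refinement → morphological
   cleanup → largest component → minimum-volume floor) producing a binary
   deposit mask an operator can still correct (`merge_manual_correction`).
2. **Morphometry** — volume *V* (µl), surface area *A* (mm²) and the
   sphericity

   $$S = \frac{\pi^{1/3}\,(6V)^{2/3}}{A},$$

   the surface area of the equal-volume sphere divided by the deposit's
   actual surface area: 1 for a sphere, smaller for flatter or lobed
   shapes. Surface area comes from a configuration-weighted boundary-voxel
   count calibrated on digitized spheres, cross-checked by a marching-cubes
   mesh estimator.
3. **Kinetics** — per deposit, the observed peak (*V*<sub>max</sub>,
   *T*<sub>max</sub>), the swelling amplitude (*V*<sub>increase</sub>,
   *V*<sub>max_rel</sub>), and the degradation half-life
   *T*<sub>1/2</sub> = ln 2 / λ from an exponential fit
   *V*(*t*) = *V̂*·e<sup>−λ(t−T<sub>max</sub>)</sup> to the post-peak
   measurements (log-linear least squares, optional nonlinear refinement;
   non-decaying deposits are censored, never given negative half-lifes).
4. **Group statistics** — one-way ANOVA with Tukey HSD post-hoc tests
   across substances, at α = 0.05.
5. **Synthetic phantoms** — OCT-like test volumes (speckled background,
   dark flat-ellipsoidal or nodular deposit, anisotropic spacing over a
   10 mm × 10 mm lateral field) with exact ground-truth masks, plus
   simulated swell-then-decay volume series and whole study cohorts, so
   every stage is validated against known truth.

Volumes are read and written as multi-page TIFF or NIfTI-1 with physical
voxel spacing; measurement and report tables are CSV.

## Worked example

```python
import numpy as np
from depotmetry import (PhantomSpec, generate_phantom, segment_deposit, measure,
                        KineticsSimSpec, simulate_volume_series, fit_half_life,
                        dice_coefficient)

# a nodular deposit phantom with fully developed speckle
spec = PhantomSpec(deposit_kind="nodular", size_params=(5, 800.0, 600.0), seed=1)
volume, truth = generate_phantom(spec)
mask = segment_deposit(volume)
print("Dice vs ground truth:", round(dice_coefficient(mask, truth), 3))
morph = measure(mask)
print(f"V = {morph.volume_ul:.2f} ul, A = {morph.surface_mm2:.2f} mm2, S = {morph.sphericity:.3f}")

# a simulated 24-week volume course and its half-life fit
series = simulate_volume_series(KineticsSimSpec(
    v0=20.0, swell_fraction=0.75, t_max=4.0,
    decay_rate=np.log(2) / 25.0, noise_cv=0.05, seed=1))
print(fit_half_life(series).summary())
```

prints

```
Dice vs ground truth: 0.98
V = 4.99 ul, A = 14.76 mm2, S = 0.958
Deposit volume kinetics
===========================================
V0 (ul)                               20.32
V_max (ul)                            35.54
T_max (weeks)                           4.0
V_increase (ul)                       15.22
V_max_rel (%)                         174.9
decay rate (1/week)                 0.02643
T_1/2 (weeks)                         26.23
fit R2 (log scale)                   0.9667
fit points                                8
censored                              False
method                            loglinear
```

The segmenter recovers the hidden deposit with Dice 0.98; its five-lobed
shape gives a sphericity below 1; and the fitted half-life (26.2 weeks)
recovers the generating value (25 weeks) to within the 5% measurement
noise of the simulated series.

The same stages are scriptable from the shell:

```bash
depotmetry simulate --kind nodular --seed 1 --out work/
depotmetry segment --in work/phantom.tif --out work/mask.tif
depotmetry measure --mask work/mask.tif
depotmetry kinetics --table work/volume_series.csv
depotmetry run --config study.yaml --out report/   # full pipeline
```

`depotmetry run` executes segmentation → morphometry → kinetics → group
statistics over a whole study configuration and writes per-deposit
measurements, per-substance kinetic summaries (mean ± SD of V0,
V_increase, V_max, V_max_rel, T_max, T_1/2), pairwise half-life
comparisons and a sphericity-over-time table.

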