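# cardiomap

Optical-mapping analysis of myocardial conduction in embryonic hearts.

During early heart development, cardiomyocytes derived from the first heart
field (FHF, outer ventricular curvature) and the second heart field (SHF,
inner curvature and outflow tract) differ in how fast and how uniformly they
conduct the electrical impulse.  Optical mapping — imaging a
transmembrane-potential-sensitive dye (e.g. di-8-ANEPPS) with a high-speed
camera at ~2,000 frames/s — makes this functional partitioning measurable:
fast, multidirectional coupling in FHF-derived outer-curvature myocardium
versus slower, more linear coupling elsewhere.

`cardiomap` implements the complete analysis chain for such recordings:

1. **Activation-time map** — per pixel, the local activation time T(x, y) is
   the time the normalized action-potential trace first reaches 50% of its
   amplitude during the depolarization phase (linearly interpolated between
   frames, with rising-phase gates to reject noise blips).
2. **Conduction-velocity vector field** — a second-order polynomial surface
   T(x, y) ≈ a·x² + b·y² + c·xy + d·x + e·y + f is fitted by least squares in
   a local window around each pixel; the velocity follows from inverting the
   travel-time gradient,

       v = ∇T / |∇T|²,   so   |v| = 1 / |∇T|,

   pointing in the direction of propagation.  Vectors and speeds are averaged
   in 16 × 16-pixel ROIs (≈35 × 35 μm²).
3. **Angle analysis** — vector angles are measured counterclockwise from a
   unit vector defined by the heart's geometry (atrial inner curvature →
   outflow tract), binned into 22.5°-wide intervals as frequency polar plots
   (radial coordinate: % of vectors per bin), and summarized per region as
   the circular angle standard deviation sqrt(−2 ln R) in degrees.
   Group comparisons use two-tailed unpaired t-tests (two groups) or one-way
   ANOVA with Tukey's post test (more).
4. **Heart-field morphometry** — the FHF reporter-area fraction of the
   ventricle, |reporter ∩ ventricle| / |ventricle|, from binary mask pairs;
   and the photoconversion accrual percentage, 100 · n_new / (n_new +
   n_converted), from nuclei count tables.
5. **Synthetic ground truth** — a kinematic wave generator (planar, radial,
   and two-region isotropic/anisotropic scenarios) renders prescribed
   activation fields into noisy dye movies with known velocity fields, so the
   entire pipeline is validated by parameter recovery.

## Worked example

Two abutting tissue regions — fast and isotropic (8 μm/ms, multidirectional
wavefront) next to slow and anisotropic (2 μm/ms, nearly linear) — imaged at
a signal-to-noise ratio of 10:

```python
import numpy as np
import cardiomap as cm

spec = cm.two_region_study_spec(seed=1)
truth, movie = cm.simulate(spec)
amap = cm.activation_map(cm.normalize_pixels(movie))
field = cm.velocity_field(amap)

rois = cm.roi_table(cm.roi_summaries(field, roi_size=16))
b = spec.boundary_col
fast = rois[rois.col_stop <= b].mean_speed.mean()
slow = rois[rois.col_start >= b].mean_speed.mean()
print(f"fast region: {fast:.2f} um/ms (true 8.0)")
print(f"slow region: {slow:.2f} um/ms (true 2.0)")

d = cm.principal_direction((0.0, 0.0), (1.0, 0.0))
cols = np.indices(field.validity.shape)[1]
sd_iso = cm.angle_variability(cm.relative_angles(cm.apply_mask(field, cols < b), d))
sd_aniso = cm.angle_variability(cm.relative_angles(cm.apply_mask(field, cols >= b), d))
print(f"angle s.d.: isotropic {sd_iso:.1f} deg, anisotropic {sd_aniso:.1f} deg")

hist = cm.polar_histogram(cm.relative_angles(field, d))
print(f"histogram: {hist.n_bins} bins, top bin {hist.freq_percent.max():.1f}%")
```

prints

```
fast region: 7.99 um/ms (true 8.0)
slow region: 2.03 um/ms (true 2.0)
angle s.d.: isotropic 7.3 deg, anisotropic 2.3 deg
histogram: 16 bins, top bin 53.1%
```

Both region speeds are recovered within 2% despite the noise; the isotropic
region's larger angle s.d. is the quantitative signature of multidirectional
coupling.  The same pipeline runs from the shell:

```sh
cardiomap simulate --scenario planar --speed 10 --seed 1 --out run/
cardiomap all --run-dir run/
```

which writes the movie, activation map, vector field, ROI and angle tables,
five figures (vector-field map, speed bars, vector and frequency polar
plots, angle-variability chart), a `summary.json`, and a `manifest.json`
recording configuration, seed and per-stage results.

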