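# Methods

## Signal model and conventions

Frames are indexed `[frame, row, col]`; physical coordinates are y-up
(`x = col · pixel_size`, `y = (n_rows − 1 − row) · pixel_size`), so all
angles are standard counterclockwise degrees and polar plots follow the
mathematical convention.  Voltage-sensitive dyes of the di-8-ANEPPS family
*decrease* in fluorescence on depolarization; normalization sign-flips
negative-polarity traces first, then rescales each pixel trace to span
[0, 1].  Pixels whose raw intensity range falls below `min_range` are
excluded.  The default `min_range` is 5× a robust noise estimate — the
median over pixels of the Gaussian-consistent MAD of the per-pixel first
temporal difference (`1.4826 · MAD / √2`) — because dim or dye-free pixels
otherwise normalize pure noise into full-scale "signals".  No temporal or
spatial filtering is applied by default; an optional odd-width moving
average is available (`smooth_temporal`), and recordings are assumed to
contain one analyzed beat (no ensemble averaging, no multi-beat
segmentation).

## Activation detection

The local activation time is the first upward crossing of 0.5 on the
normalized trace that lies inside a contiguous depolarization upstroke:
walking backward from the crossing, the trace must fall below the lower gate
(default 0.25) before ever exceeding the upper gate (default 0.75), and
walking forward it must rise above the upper gate before ever falling below
the lower one.  The gates reject isolated noise excursions through the
half-amplitude level while leaving genuine upstrokes untouched; they are
configurable because only the 50% criterion itself is fundamental.  The
crossing time is linearly interpolated between the bracketing frames —
exact for a linear-ramp upstroke and unbiased for fast upstrokes sampled at
2,000 frames/s.  Pixels without a qualifying crossing are flagged invalid,
never raised as errors.

Both action-potential templates of the synthetic generator (linear ramp and
a symmetric truncated-logistic sigmoid) cross half amplitude exactly half an
upstroke after onset, so noiseless recovery tests compare detected times
against `T + upstroke/2` analytically; the uniform offset cancels in every
spatial gradient and velocity.

## Velocity estimation

A quadratic surface `T ≈ a x² + b y² + c xy + d x + e y + f` is fitted by
ordinary least squares over a `(2·half_width + 1)²` window in
window-centered physical coordinates, so `∇T = (d, e)` at the pixel.  The
default `half_width = 2` (5×5 pixels) is the smallest window giving a
comfortable margin over the 6 fitted coefficients while staying local
relative to the ≈50 μm structures of interest; it is configurable.  Windows
with fewer than 6 valid pixels or a rank-deficient design (collinear valid
pixels) yield no vector.  Fits whose residual RMS exceeds 10% of the
window's activation-time span are rejected — a scale-free bound that adapts
to local wave speed and removes detection outliers without touching clean
planar regions (whose residuals are at machine precision, since a plane lies
inside the quadratic model space; planar recovery is therefore exact to
rounding).

The velocity is `v = ∇T / |∇T|²`, the inverse-gradient estimator for a
travel-time field; `|v| · |∇T| = 1` holds identically at every reported
vector.  Gradient magnitudes below `1e-6 ms/μm` (speeds above 10⁶ μm/ms)
mark wavefront collision/breakthrough sites and are reported invalid rather
than as numbers.

ROI summaries tile the valid bounding box with `roi_size × roi_size` squares
(default 16 px ≈ 35 μm at 2.2 μm/pixel); speed is averaged arithmetically,
angles by the circular mean, since naive averaging of wrapped angles is
meaningless across the 0°/360° seam.

## Angle analysis

The geometric reference is the unit vector from the atrial inner-curvature
landmark to the outflow-tract landmark (the principal direction of
propagation, earliest → latest activation).  Landmarks are user-supplied
coordinates; `landmarks_from_activation` offers the argmin/argmax of T as a
fallback but never silently overrides supplied landmarks.  Angles are
wrapped to [0, 360) and binned into half-open 22.5° intervals (16 bins); an
angle exactly on an edge joins the higher bin, 360° wraps to 0°, and the
percent frequencies sum to 100 for any non-empty input.

Angle variability defaults to the circular standard deviation
`sqrt(−2 ln R)` in degrees, computed as `R = mean(cos(θ − μ))` about the
circular mean μ — algebraically the mean resultant length, but exact
(s.d. = 0) for zero-dispersion input where the naive `|mean e^{iθ}|` loses a
few ulps.  `R = 0` (perfectly balanced angles) has no defined s.d. and
returns NaN with a warning.  An arithmetic variant (sample s.d. of
deviations wrapped to (−180, 180]) is available behind `method="arithmetic"`
for sensitivity analysis; the two agree in the small-dispersion limit.
Reports name the method used.

Group comparisons use the classical linear tests (two-tailed unpaired
t-test; one-way ANOVA with Tukey's HSD for >2 groups) rather than circular
hypothesis tests, matching how regional statistics are conventionally
compared in this setting; ROI-level angles entering comparisons are circular
means per ROI.  Zero-variance inputs are flagged `degenerate`.

## Synthetic data: what it emulates and what it does not

The generator prescribes an activation field T(x, y) kinematically and
renders `baseline ± amplitude · AP(t − T) + N(0, noise_sd²)` at 2,000
frames/s, 2.2 μm pixels, negative polarity — the acquisition geometry the
pipeline targets.  Scenarios:

* **planar** — T = (p · d̂)/speed; velocity `speed · d̂` everywhere.
* **radial** — T = |p − center|/speed; outward velocities, undefined at the
  source pixel.
* **two_region** — propagation along +x with per-region slowness,
  continuous across the boundary.  Anisotropy is modelled kinematically as
  direction-dependent slowness: a transverse sinusoidal wavefront
  undulation `T = B(x) + A(x) sin(2πy/λ)` whose maximum angular deviation is
  `undulation_deg / anisotropy_ratio` per region and whose amplitude ramps
  to zero at the boundary (keeping T continuous).  Isotropic regions
  (ratio 1) therefore show multidirectional vectors, anisotropic regions
  nearly linear ones — the pattern contrast the angle statistics must
  resolve — while the default `undulation_deg = 0` leaves the field exactly
  piecewise planar.

The fixed study conditions for the two-region comparison
(`two_region_study_spec`: 64×96 grid, speeds 8 and 2 μm/ms, anisotropy
ratios 1 and 3, 15° undulation with 50 μm period, SNR 10, i.e. noise sd =
amplitude/10) were chosen once as a realistic embryonic-heart contrast: a
4:1 speed ratio spans the observed fast/slow range, SNR 10 is attainable
with potentiometric dyes at these frame rates, and the grid provides ≥12
complete 16-px ROIs per region.

Not emulated: reaction–diffusion electrophysiology (wavefront curvature and
source–sink effects), photobleaching, motion artefacts, optical blurring,
repolarization, and multi-beat rhythms.  Passing recovery tests therefore
demonstrates the correctness of the analysis chain on well-posed wave data,
not robustness to contraction artefacts or complex arrhythmic activation —
on real recordings those must be controlled upstream (e.g. motion arrest)
as is standard for this preparation.

Morphometry fixtures: the ventricle is a filled ellipse; the reporter
territory is the contiguous blob of ventricle pixels nearest a seeded anchor
sized to the requested area fraction (exact to within one pixel); nuclei
tables carry exactly the requested converted/new totals in shuffled order.

## Determinism and numerics

All randomness flows from explicit integer seeds (`numpy`
`default_rng`/`SeedSequence`; the CLI splits one top-level seed per use), so
identical configuration reproduces byte-identical CSV outputs.  Least
squares uses `numpy.linalg.lstsq` with rank checking; the independent test
oracle solves the normal equations directly.  Degenerate inputs (constant
traces, empty masks, zero gradients, coincident landmarks, balanced angle
sets) are either flagged invalid or raised as `ValueError` at construction,
per the rule that per-pixel failures flag and argument errors raise.

Problem sizes in the tests and the acceptance script (32×32 planar grids,
12 directions; the 64×96 two-region study grid; 200 random fit windows;
1000 random angle sets) were chosen to exercise every code path with
thousands of pixels per condition while keeping a full validation run in the
tens of seconds on one CPU.

## Known limitations

* Velocity estimates are biased upward near high noise because speed is a
  convex function of the gradient; the two-region recovery stays within a
  few percent at SNR 10, but lower SNR inflates fast-region speeds first
  (small gradients are noise-sensitive).
* The 50% criterion assumes a monotone upstroke between the gates; strongly
  fractionated potentials would need the optional temporal smoothing.
* Min–max normalization uses trace extremes and thus inherits noise in the
  amplitude estimate; at SNR ≥ 10 the induced timing jitter is well under
  half a frame (tested), but very low SNR would call for percentile-based
  amplitude estimation.
* ROI tiling is axis-aligned and anchored at the valid bounding box;
  user-drawn ROI support is limited to supplying masks.
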