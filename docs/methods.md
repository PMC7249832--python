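# Methods

This document describes the simulation model, the estimators, the
calibrated default parameters, and the numerical choices behind them.

## 1. Simulation model

### 1.1 Stage

Three axes driven in whole actuator steps — 70 nm in x and y, 50 nm in z —
over a 12 × 12 × 4 mm travel range. Commanded positions are given in
nanometres relative to the centre of travel, quantized with
round-half-to-even, and clamped to ±travel/2 (with a `clamped` flag).
Two imperfections are modelled:

* **Backlash** (slot model). The carriage sits in a slot of
  `backlash_steps` steps of lost motion: its physical position is confined
  to `[commanded, commanded + backlash]`. Moving in the positive direction
  engages the carriage exactly at the commanded position; a reversal
  leaves it lagging by up to the slot width. Approaching every target from
  the same direction (here: from below in z) therefore cancels backlash,
  which is how the autofocus and z-stack code moves.
* **Drift**. The physical position gains `drift_rate_nm_per_hour`
  per elapsed hour of simulated wall-clock time, independent of any moves.
  The microscope facade keeps that clock: moves take
  `distance / move_speed + settle_time`, captures take one exposure.

### 1.2 Optics

The point-spread function is a Gaussian parameterized by its full width at
half maximum (FWHM). Defocus adds width linearly:

    blur_fwhm(dz) = psf_fwhm + defocus_blur_coeff * |dz|

with `defocus_blur_coeff = 0.2` nm of FWHM per nm of defocus by default.
The depth-of-focus proxy used by tests is the defocus at which the blur
grows 10%: `0.1 * 480 / 0.2 = 240 nm` for the default preset.

Two image-formation modes exist. In the default **coherent** mode the
specimen amplitude (square root of intensity) is convolved with the
amplitude PSF and the result squared, so a knife edge renders as
`(step ⊛ amplitude-PSF)²`; the edge-analysis pipeline's square-root step
exactly inverts this. The **incoherent** mode convolves intensity
directly and exists for sensitivity experiments.

Vignetting is a radial quadratic gain falling to `vignetting_falloff` at
the image corner. Radial distortion follows the single-coefficient model
`r' = r (1 + k r²)` with r normalized to the image half-diagonal;
rendering inverts it with a few Newton steps so the specimen is sampled at
undistorted coordinates.

Presets: `0.65NA-dry` (480 nm FWHM, 100 nm/px) and `1.25NA-oil`
(250 nm FWHM, 60 nm/px).

### 1.3 Camera

8-bit output, default 820 × 616 sensor at ~100 nm/px (≈ 350 × 262 µm field
of view — the pixel-size calibration on the simulator reproduces both
numbers). Noise is a Gaussian approximation to shot noise
(`shot_noise_scale · sqrt(counts)`, default scale 0.2) plus Gaussian read
noise (default σ = 1 count). Optional Bayer sampling mosaics the RGB image
(RGGB) and demosaics bilinearly, halving per-channel sampling density.
Every frame also passes once through a real JPEG encoder (Pillow, default
quality 85); the byte size is stored on the frame and is what the fast
autofocus consumes.

Reproducibility: every render draws its noise from
`default_rng([scope_seed, frame_counter])`, so entire acquisition runs are
bit-for-bit repeatable.

### 1.4 Specimens

Flat virtual slides with a planar focal surface
`z_focus(x, y) = a·x + b·y + c` (tilted specimens, focus gradients).
Canned scenes:

* **blood-smear** — Poisson-placed absorbing disks (density
  6000 cells/mm², radii 3–4.5 µm, central pallor) over a bright
  background, multiplied by a seeded sub-resolution value-noise texture
  (amplitude 0.12, 700 nm scale). The texture is essential: a
  piecewise-flat specimen compresses *better* in focus (blur adds
  mid-frequency content; JPEG size then anti-correlates with focus).
  With partially-resolved granularity, both the Laplacian score and the
  compressed frame size peak at focus, which is the mechanism both
  autofocus methods rely on. These parameters were fixed before the
  acceptance measurements and are recorded as study conditions.
* **knife-edge** — a straight edge, default 1° from vertical, for PSF and
  distortion calibration.
* **grid** — periodic dark lines for pixel-size calibration.
* **flat** — uniform field for shading calibration.

The texture is a deterministic function of absolute sample coordinates, so
overlapping scan tiles see identical structure — required for stitching.

## 2. Estimators

### 2.1 Autofocus

**Laplacian sweep.** Sample `n` z positions across a range (visited in
ascending order after an initial overshoot below the range, so every
position — including the final move to the peak — is approached from the
same direction, cancelling backlash). The score is the mean squared
response of the 3 × 3 Laplacian kernel `[[0,1,0],[1,−4,1],[0,1,0]]` over
the valid interior. The best z is the parabolic vertex through the three
samples around the arg-max; a peak at either end of the range sets
`at_boundary` and skips refinement.

**Compressed-frame-size fast autofocus.** The stage sweeps the range
bottom-to-top at constant speed while the camera streams at its frame
rate; each frame's JPEG byte size is recorded, smoothed with a 5-point
moving average, and the peak frame is mapped back to z through the
constant-velocity time→position model (optionally shifted by a camera
latency). Fewer than 5 frames raises an error advising a slower sweep; a
flat size curve (relative variation below 5%) raises "no focus found"
rather than returning an arbitrary position.

The two methods agree within one sweep spacing on the smear scene (tested
property).

### 2.2 Knife-edge PSF estimation

1. **Edge detection.** Per row, the 50% crossing of the smoothed
   intensity profile near the maximum gradient, to sub-pixel precision;
   at least 80% of rows must yield a crossing.
2. **Pooling.** Each row's samples are re-centred on its own crossing.
   The 1° edge tilt makes the crossings slide across the pixel grid, so
   the pooled (offset, intensity) cloud samples the edge profile far
   denser than the pixel pitch.
3. **Binning + spline.** The cloud is averaged in bins of pitch/8 (count-
   weighted), then fit with `scipy.interpolate.make_smoothing_spline`.
4. **Differentiation.** The profile is renormalized on its plateaus,
   square-rooted (inverting the coherent intensity model), differentiated,
   and the FWHM read off the half-maximum crossings by linear
   interpolation. A `resolution_limited` flag is set when the recovered
   width is below 2 pixels.

**Numerical choice — fixed λ instead of GCV.** Choosing the spline
roughness penalty by generalized cross-validation is the obvious default,
but on this data it is catastrophically unstable: the pooled samples carry
8-bit quantization structure that GCV chases, and recovered widths swung
between 26 nm and 580 nm for a 480 nm truth. The default is therefore a
fixed penalty λ = 1e6 (nm³), calibrated once on noise-free edges of width
300–1000 nm (bias ≤ +3.2% over that range; with default noise the 480 nm
preset recovers 491–500 nm across seeds, within the 5% tolerance).
GCV remains available via `smoothing="gcv"`.

### 2.3 Radial distortion

A straight edge is translated to (default) 9 lateral positions spanning
80% of the field of view; edge points are detected at each. For a trial
coefficient k every point set is undistorted and fit with a
total-least-squares line; `k` minimizes the pooled squared perpendicular
residuals (bounded scalar minimization over k ∈ [−0.2, 0.2]). Lines
through the image centre carry no radial signal and are rejected as
degenerate geometry. The headline number is the worst-case displacement
`|k| · R` at the corner (R = half-diagonal) as a percentage of the field
width. Recovery is linear: estimated vs injected k has slope 1 ± 0.05
over k ∈ [−0.02, 0.03] (tested property); the distortion-free simulator
reports ~0.005%.

### 2.4 Lens shading and pixel size

The shading table is a (default) 32 × 24 grid of per-cell gains,
`brightest cell mean / cell mean`, normalized so the minimum gain is
exactly 1; correction bilinearly upsamples the cell-centre grid
(`map_coordinates`) and reports saturated pixels. The round-trip property
(vignetting 0.7 → correct → flat to 1% RMS) is evaluated on cell means:
per-pixel RMS would measure irreducible shot noise (~1.6%), not shading.

Pixel size comes from a grid target of known pitch: the period in pixels
is the first autocorrelation peak of the row/column-averaged profiles
(parabolic sub-sample refinement), giving nm-per-pixel and the field of
view.

### 2.5 Sampling adequacy

With a Bayer mosaic, a 2 × 2 block forms one full-colour sample, so the
effective sampling pitch is twice the pixel pitch (200 nm at 100 nm/px);
sampling is judged adequate when the effective pitch is below the
resolution FWHM (480 nm).

## 3. Scanning and stitching

Grid scans are laid out with site spacing `fov · (1 − overlap)` (snake
order by default; it provably shortens travel vs raster), an autofocus
policy per site, and symmetric z-stacks captured bottom-to-top. A failed
autofocus (e.g. a featureless field) falls back to a plane fit over
previously focused sites — the thin flat-sample assumption — and flags the
site in the manifest. Time-lapse is a degenerate plan: one site, timed
captures, optional refocus per frame; with refocusing, drift-induced focus
error stays bounded by the sweep spacing while it grows without bound
otherwise (tested property).

Stitching registers grid-adjacent tile pairs on their nominal overlap
windows. Plain phase correlation is biased toward zero lag here: smear
cells are 60–90 px wide, so the unnormalized correlation surface is nearly
flat over a few-pixel lag and the larger overlap area at zero lag wins.
The integer shift therefore comes from masked normalized cross-correlation
(Padfield), which normalizes by the overlap at each lag; a plain upsampled
phase correlation on the re-aligned windows adds sub-pixel refinement, and
a Pearson-correlation quality gate falls back to the nominal offset (and
flags the pair) when the overlap carries no signal. Global tile positions
solve the pairwise-offset graph by least squares, anchored at the first
tile — robust to any single bad pair. Only the central crop of each tile
is composited; gap-free mosaics need `crop_margin_fraction ≤ overlap / 2`.
Verified properties: a zero-noise 2 × 2 mosaic equals the matching window
of one large render pixel-for-pixel, and ±4-px stage jitter is recovered
to ≤ 1 px.

## 4. Problem sizes and runtimes

Tests run on reduced sensors (120 × 90 to 400 × 300 px) because the
physics is resolution-independent; the full suite (139 tests, including
all CLI end-to-end paths) takes ~20 s on one CPU.
`scripts/acceptance.py` takes ~2 s. The full-sensor default
(820 × 616) renders in well under a second per frame.

## 5. Known limitations

* The specimen is flat and purely absorbing; no 3-D structure, phase
  effects, or diffraction beyond the Gaussian-PSF approximation.
* Defocus blur is symmetric in ±z and linear in |dz|; real aberrations
  are neither.
* Shot noise is Gaussian, adequate at the default signal levels but wrong
  in the few-photon regime.
* The Bayer model is mosaic + bilinear demosaic only.
* The stage model has no vibration, hysteresis beyond the backlash slot,
  or axis cross-talk.
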