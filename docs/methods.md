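# Methods

This note records the models, numerical choices and known limitations of
`ommap`, in the order the pipeline runs.

## Synthetic movies

The generator exists so that every downstream stage can be checked against
ground truth. A scene is a conduction-speed field on a pixel grid (a base
speed with rectangular or disk-shaped overrides), an optional set of block
line segments across which activation cannot propagate, and a pacing source
(one of the four grid edges, mirroring epicardial pacing-wire placement, or
a point).

**Front propagation.** True activation times are first-arrival times of the
eikonal equation |∇T| = 1/v, solved by fast marching with upwind quadratic
updates on both the axis-aligned stencil (spacing h) and the 45°-rotated
stencil (spacing h√2), so all 8 neighbors inform each update. The local
travel cost is `pixel_size/speed`. The rotated stencil matters: a plain
8-neighbor shortest-path scheme overestimates oblique travel times by up to
1/cos(22.5°) − 1 ≈ 8 %, while this solver stays well under one pixel of
travel time on a 50 × 50 point-source scene (measured max error ≈ 0.45 px).
Edges crossed by a block segment are severed in both stencils; pixels the
front never reaches — or reaches too late for the movie length — are flagged
in the ground truth rather than silently truncated.

**Traces.** Each activated pixel gets V(t) = up(t)·rec(t) with a logistic
upstroke whose maximum slope falls exactly at the pixel's activation time
(10–90 % rise time = `upstroke_ms`, default 2 ms), a plateau of `apd_ms`
(default 100 ms) and an exponential recovery (τ = apd/5). Only the upstroke
timing matters downstream; the rest of the waveform is a plausible shape,
not an ionic model. Upstrokes are delayed by 3 × upstroke_ms so the sigmoid
foot is recorded.

**Noise and drift.** Additive white Gaussian noise per pixel-frame
(`noise_sd`, default 0.05 of the unit AP amplitude) and a linear baseline
ramp (`drift_per_s`, default 0.1/s). No recorded noise spectra were
available to calibrate against, so both are deliberately minimal structures
— exactly what the preprocessing stage claims to remove — and both are
config keys. Real recordings additionally contain motion residue, spatially
correlated shot noise and illumination inhomogeneity; passing tests on
these movies therefore validates the pipeline's logic and numerics, not its
robustness to every laboratory artifact.

**Geometry defaults** mirror the emulated acquisition: 100 × 100 pixels,
0.17 mm pitch (17 mm field of view, 0.0289 mm² per pixel), 3000 frames/s,
1500 frames (500 ms).

**Study tables.** The clustered-outcome generator produces one row per
(animal, pacing position, S1/S2 train) cell: fixed-effect cell mean +
a per-animal normal random intercept + normal residual. Defaults mirror the
emulated study layout: 3 control + 4 persistent-AF animals × 4 positions ×
2 trains, with user-specified missing cells (one missing cell gives the
55-row layout). `animal_sd² / (animal_sd² + resid_sd²)` is the true ICC.

## Preprocessing

* **Spatial binning** — convolution with a normalized Gaussian kernel,
  σ = kernel_size/4 truncated to kernel_size × kernel_size (3 or 5),
  borders by edge replication. Only the kernel size is conventionally
  reported for this operation; σ and truncation are this package's choice.
* **Temporal filter** — 4th-order Butterworth low-pass at 100 Hz applied
  forward-backward (`sosfiltfilt`), i.e. a 0–100 Hz band-pass with exact DC
  gain and zero phase, so upstroke times are not shifted. Family and order
  are config keys.
* **Drift correction** — per pixel, a grayscale opening (running minimum
  then maximum, window `drift_window_ms`, default 200 ms) erases the AP
  humps; a polynomial (default order 2) is least-squares fitted to the
  opened trace and subtracted. The opening window must exceed one AP
  duration (upstroke + plateau + early recovery); 200 ms covers the default
  100 ms plateau comfortably. Iteratively reweighted baseline fits were
  rejected: with a polynomial basis and long plateaus they admit degenerate
  fixed points that dip below the true baseline.
* **Normalization** — affine min → 0, max → 1 per pixel; constant traces
  map to zeros rather than dividing by zero.
* **SNR mask** — per pixel, SNR = (peak-to-peak of the 20 ms running mean)
  / (robust noise σ from median absolute successive differences of the
  high-frequency residual). The half-window at each trace end is excluded
  from the amplitude: there the running mean leans on replicated samples
  and its noise floor roughly quadruples, which would otherwise let pure
  noise pixels reach SNR ≈ 2. With the exclusion, pure-noise pixels measure
  SNR < 1 and noise-free active pixels hit the 10⁹ cap. The default
  threshold 3.0 is a config key and is archived with every run; no
  published threshold exists for the instrument emulated here.

## Activation times

LAT = time of maximum temporal derivative of the normalized trace within
the analysis window (one beat per call; the caller supplies the window, by
convention the last S1 and the following S2). The derivative peak is
refined by a 3-point parabolic fit, since at 0.33 ms/frame integer-frame
LATs would quantize CV estimates. Pixels whose within-window amplitude is
below `amplitude_floor` (default 0.2 of the normalized range) are undefined.
A 50 %-amplitude-crossing criterion is available behind `method="level50"`;
max-dV/dt is the default because it is the standard criterion in optical
mapping.

## Conduction velocity

For each pixel with defined LAT, T(x, y) is fitted by least squares over a
circular neighborhood (default radius 3 px, order 2 — the classic
polynomial-surface approach for activation maps). With T in ms and x in mm,
ms/mm ≡ s/m, so v = ∇T/|∇T|² is in m/s directly. Degenerate cases are
flagged, not guessed: neighborhoods with fewer defined pixels than
coefficients are "underdetermined"; |∇T| below 10⁻⁶ s/m is "flat gradient"
(quasi-simultaneous activation); speeds above 2.0 m/s are "implausible".
All three are excluded from region statistics, and their counts are logged.
Full neighborhoods share one precomputed pseudo-inverse (a batched
least-squares fast path); ragged neighborhoods fall back to per-pixel
`lstsq`.

## Slow-conduction regions

Strict threshold: valid speed < 0.2 m/s is slow, ≥ 0.2 m/s is normal,
invalid/unmasked is excluded. Components are labeled with 4-connectivity
(horizontal/vertical neighbors only, no diagonals). The percent-SC outcome
counts every slow ROI pixel, including isolated singles; the component
count and areas include only components of ≥ 2 pixels; mean area over zero
counted components is reported as undefined (NaN), not 0. The ROI
denominator is the SNR mask intersected with valid-CV pixels — the mask a
reader of the maps would consider analyzable — and this choice is recorded
in each report's metadata.

## Study statistics

* **Descriptives** — mean ± sample SD (n − 1), rounded half-up to integers;
  groups with < 2 values get an undefined SD and a flag.
* **Mixed model** — REML linear mixed model with a random intercept per
  animal and fixed effects class + train + position + class×train +
  class×position (9 predictor terms). Adjusted (marginal) means for a
  factor level are computed by pinning that factor and averaging the design
  matrix over the observed rows — mean centering of all other terms.
  Contrasts (class, train overall and within each class, joint position
  test) are Wald z / χ² tests on those linear combinations. A singular fit
  returns ICC 0 with a convergence note instead of raising. No
  degrees-of-freedom small-sample correction is applied; with 7 clusters
  the Wald intervals are mildly liberal (measured coverage ≈ 94–95 % at
  nominal 95 % in the recovery simulations).
* **Clustering summary** — ICC = σ²_animal/(σ²_animal + σ²_resid),
  D_eff = 1 + (m − 1)·ICC with m the average cluster size, effective sample
  size n/D_eff rounded to the nearest integer (half-up; floor/ceil are
  config options).

## Problem sizes used in validation

Unit tests run on 24–60 px grids with 300–600 frames; the end-to-end
recovery and velocity-oracle checks use the full 100 × 100 geometry; the
mixed-model recovery uses 500 simulated 55-row tables (200 in the
acceptance script). These sizes were chosen as the smallest at which the
discretization effects under test are visible.

## Known limitations

* No motion correction or ratiometric dye correction (the emulated
  preparation suppresses motion pharmacologically).
* One beat per call; no automatic beat segmentation.
* No conduction-block *line* extraction — block shows up as flagged
  flat-gradient/implausible pixels and LAT discontinuities for manual
  inspection.
* No fiber-direction or anisotropy inference.
* Parity with any specific acquisition vendor's processing chain is not
  claimed; equivalence is demonstrated on synthetic ground truth only.
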