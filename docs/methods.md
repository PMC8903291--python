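# Methods

## FRAP model and correction

A granule FRAP trace consists of three per-frame ROI means: the bleached
granule `B(t)`, an unbleached reference granule `U(t)`, and diffuse
cytoplasm `Bg(t)`, with `n_pre` pre-bleach frames (default 2) acquired at
`dt = 1.0878 s` and 200 post-bleach frames. The underlying recovery model
is a one-phase association,

    S(t) = Y0 + (P − Y0)(1 − exp(−K (t − t0))),   K = ln 2 / t½,

with `Y0 = 100(1 − bleach_depth)` and `P = Y0 + Fm (100 − Y0)` on a scale
where the pre-bleach signal is 100. The four-step correction (PCV → CAI →
BCFI → FCV, see the `frap` module docstring) has one exact algebraic
property that the test suite verifies: if both granule ROIs are multiplied
by the same per-frame acquisition-photobleaching factor `d^t`, the PCV step
cancels it identically, so the FCV of a drift-only trace is flat at 100 to
machine precision. This exactness holds when the background ROI reads the
offset-free baseline; a large constant additive offset shared by all ROIs
is *not* cancelled by a multiplicative correction applied before background
subtraction, which is why the noiseless reference simulations use zero
background level while the noisy-realism defaults carry a nonzero one.

Fitting is nonlinear least squares over post-bleach FCV with `t0` at the
first post-bleach frame (the sub-second bleach interval is not modelled).
Initial guesses: `Y0` = first post-bleach value, `P` = mean of the last 10
frames, `K` from the time to mid-recovery; bounds `K ∈ (1e−6, 10] s⁻¹`,
`P ≤ 200`. Non-convergence returns best-effort parameters flagged
`converged=False` rather than raising. Two recovery conventions exist in
the literature — the plateau `P` (percent of pre-bleach recovered) and the
bleach-depth-normalized mobile fraction `Fm = (P − Y0)/(100 − Y0)`; both
are reported, and they coincide for a complete bleach, which is what the
reference simulations use.

## Synthetic scenes

Every generator is seeded (`numpy.random.default_rng(seed)`, no global
state) and returns a ground-truth record sufficient to score the matching
analysis. The noise model everywhere is Poisson shot noise on the rendered
signal plus additive Gaussian read noise (sd 3 counts on a 50-count
cytoplasm by default); `snr` is defined as peak amplitude above background
divided by the background standard deviation `sqrt(background + read_sd²)`.
Scenes use 0.084 µm pixels, so the 3×3 px minimum granule is 0.252 µm.

What the generators emulate — and what they do not: granules are Gaussian
spots (isotropic, or elongated at axis ratio ≥ 3 with conserved area for
amorphic blobs) placed without overlap by rejection sampling; there is no
optical PSF model, no depth structure, no autofluorescence texture, and
touching/overlapping granules are excluded by construction rather than
split. Transport tracks are 1-D along-axis positions with constant
per-track speed plus jitter (stationary jitter sd 0.15 µm/frame, well below
the 0.138 µm/s floor at 4.84 s frames); motor-protein pausing and direction
reversals are not modelled, and `neurite_length_um` bounds the rendered
field, not the coordinates. Passing parameter-recovery tests on these
scenes therefore demonstrates correctness of the measurement pipeline, not
robustness to every pathology of real microscopy (clumped granules,
focus drift in z, uneven illumination).

FRAP parameter recovery was measured over a grid Fm ∈ {0.1…0.9} ×
t½ ∈ {4, 12, 25, 100} s at noise sd 3 with 20 seeded replicates per cell
(the acceptance suite recomputes this); the pooled median relative error of
Fm and t½ is the reported statistic, since single cells with low mobile
fraction and half-times comparable to the 218 s acquisition window are
intrinsically noise-limited.

## Granule morphometrics

The detection threshold is `median + k·MADσ` (k default 3) of the
cytoplasm inside the cell mask, re-estimated once after masking first-pass
detections; components are 8-connected and must have area ≥ 9 px and a
bounding box admitting a 3×3 square. Detection is invariant to uniform
intensity offsets by construction.

Circularity is `4πA/P²` with the perimeter traced along the 0.5
iso-contour of the Gaussian-smoothed (σ = 0.8 px), hole-filled component
mask. The smoothing matters: raw thresholded boundaries of noisy round
granules are ragged at the single-pixel scale, and both crack-boundary and
Crofton perimeter estimates inflate enough to misclassify genuinely round
granules as amorphic. With smoothed tracing a rasterized disk scores ≈ 1.00
and elongated 1:4 shapes score ≈ 0.6–0.7. Values are capped at 1.1 because
minimal shapes (3×3 squares) overshoot on the discrete grid. The
circular/amorphic cut of 0.8 is a calibrated stand-in for a visual call and
is config-exposed; the published analysis classified morphology by eye.
Likewise, the per-image manual threshold used for granule-size measurement
in the original workflow is replaced by the same automated robust threshold
used for detection.

## Transport classification

A track is stationary when its mean frame-to-frame speed is below
`v_min = 0.138 µm/s` (the acquisition pixel size per second); otherwise
anterograde or retrograde by the sign of net displacement (positive = away
from the soma). A fast track with exactly zero net displacement is broken
to stationary and flagged. Velocity is averaged over motile frames
(instantaneous speed ≥ v_min), with the whole-track mean also emitted,
since the published convention is not stated. "Total displacement" is
emitted both as path length Σ|Δs| and as net |end − start|; bursts are
annotated descriptively as frames exceeding 3× the track's median speed and
play no role in classification. `dt` defaults to 4.84 s (484 s over 100
frames). Track linking is greedy nearest-neighbor with jump cap
`max(3·v_min·dt, 2 px)`; crossing tracks may swap identities — a documented
limitation, not an error.

## Colocalization and spots

Pearson correlation is computed over all ROI pixels with no intensity
threshold (no Costes masking), matching the plain Pearson output of
standard colocalization plugins. Rolling-ball background subtraction uses
the geometric rolling-ball algorithm (equivalent to a grayscale opening
with a ball structuring element), radius 50 px by default; the ImageJ
paraboloid variant is not replicated. Spot detection runs a
scale-normalized negative Laplacian-of-Gaussian at the PSF sigma
(default 1.3 px), keeps local maxima above `threshold_factor` (default 6)
times the MAD-σ of the filtered image, and refines positions by a 2-D
Gaussian fit in a 7×7 window, falling back to the pixel maximum when the
fit fails or wanders. Spots closer than ~2σ merge into one detection.
Thresholds were calibrated on the generator (blank-noise scenes average
≤ 1 false spot; snr 8 scenes are recovered with sub-0.5 px RMS error) and
are config-exposed. Compartment assignment is a mask lookup at the rounded
coordinate with soma precedence on boundaries; z-stacks are max-projected
before detection since per-cell totals, not z-resolved positions, are the
quantity of interest.

## Reporter normalization

Technical replicates are averaged per construct before control
normalization, and the plate (independent experiment) is the unit for the
standard error, mirroring triplicate-experiment error bars. Wells with
non-positive RLuc are excluded with a warning; a zero control ratio is
fatal. Normalized values are invariant to rescaling all FLuc or all RLuc
readings on a plate.

## Numerical and design notes

- Pixel coordinates are 0-based `(y, x)` with centers on integer
  coordinates; ROI membership is by pixel center, boundary inclusive. FRAP
  trace extraction translates a fixed pixel-offset stencil with the
  (sub-pixel) ROI center and samples bilinearly, so a followed ROI keeps
  its exact shape; ROI following re-centers on the background-suppressed
  intensity centroid of a search window each frame, and frames where the
  bleached ROI falls below the background mean are flagged as out-of-focus
  and excluded from fitting.
- Image I/O is OME-TIFF via tifffile, with axes honored from metadata and
  missing axes expanded to length 1; raw intensities are never rescaled,
  and any bit depth is accepted.
- Problem sizes in the test and acceptance suites (e.g. 12-granule scenes,
  100-track cohorts, 20-seed batteries, the 9×4×20 FRAP grid) were chosen
  as the smallest sets at which the binomial confidence intervals and
  median-error statistics are meaningful.

## Known limitations

No 3-D segmentation or sub-pixel granule tracking; no reaction–diffusion
FRAP models (single-exponential association only); no Manders/Costes
coefficients; no transcript-number deconvolution of merged smFISH spots;
proprietary microscope formats are out of scope.
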