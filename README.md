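# granulekit

Quantification of RNA-granule fluorescence microscopy, built for studies of
RNP condensates such as FMRP granules in *Drosophila* S2R+ cells and primary
motor neurons. The package turns raw image stacks, ROIs and plate readings
into the quantities such studies report — granule dynamics by FRAP, granule
counts and morphology, neurite transport statistics, colocalization,
single-molecule FISH transcript counts, and translational-repression
reporter values — and pairs every analysis with a seeded synthetic-scene
generator so each stage is verifiable by parameter recovery.

## What it computes

**FRAP double normalization and recovery fitting.** For a bleached granule,
an unbleached reference granule and a cytoplasmic background ROI, each
measured per frame, the corrected recovery profile is built in four steps:

- PCV(t) = mean(U_pre) / U(t) — the photobleach correction value from the
  unbleached granule U, cancelling shared acquisition photobleaching;
- CAI(t) = B(t) · PCV(t) — the corrected intensity of the bleached granule B;
- BCFI(t) = CAI(t) − Bg(t) — background-subtracted, per frame;
- FCV(t) = 100 · BCFI(t) / mean(BCFI_pre) — percent of pre-bleach signal.

The post-bleach FCV is fit with a one-phase association
`Y(t) = Y0 + (P − Y0)(1 − e^(−K(t − t0)))`, giving the plateau `P`, the
half-time `t½ = ln2/K`, and the bleach-depth-normalized mobile fraction
`Fm = (P − Y0)/(100 − Y0)` (equal to `P/100` for a complete bleach). Because
the PCV step cancels any shared multiplicative per-frame decay exactly,
noiseless synthetic traces recover their generating parameters to printed
precision.

**Granule morphometrics.** Detection inside a cell mask by a robust
background threshold (median + k·MAD-σ, one re-estimation pass) with the
≥ 3×3 px minimum-size rule; circularity `4πA/P²` from a traced, smoothed
boundary; cells with any amorphic (circularity < 0.8) granule are amorphic
cells; granule density is granules per µm² of `π(d/2)²` cell area from the
longest-axis diameter; distance from the soma edge with a ≥ 10 µm distal
call.

**Neurite transport.** Kymographs along a polyline neurite, greedy
nearest-neighbor track linking, and classification against a 0.138 µm/s
speed floor: stationary below it, else anterograde/retrograde by the sign
of net displacement from the soma; velocities over motile frames, path
length and net displacement.

**Colocalization and smFISH.** Pearson correlation over ROI pixels (no
thresholding), optionally after rolling-ball background subtraction
(radius 50 px); spot detection by Laplacian-of-Gaussian filtering with
sub-pixel Gaussian refinement and soma/neurite compartment assignment.

**Reporter normalization.** Per-well FLuc/RLuc, technical replicates
averaged per construct, normalized to the control construct; plates
(independent experiments) are the unit of error.

## Worked example

```python
from granulekit import analyze_trace, gen_frap_trace

raw, truth = gen_frap_trace(Fm=0.82, t_half_s=21.9, bleach_depth=1.0,
                            drift_per_frame=0.002, seed=0)
norm, fit = analyze_trace(raw)
print(fit.P, fit.t_half_s, fit.Fm)
```

prints

```
82.0 21.9 0.82
```

— a noiseless trace generated with an 82% mobile fraction and a 21.9 s
half-time under the standard acquisition (1.0878 s frames, 2 pre-bleach and
200 post-bleach frames, 0.2%/frame acquisition photobleaching) is recovered
exactly: the normalization removes the drift and the fit returns the
generating plateau, half-time and mobile fraction. The `examples/`
directory has one short script per capability (FRAP, granule morphometrics,
transport, colocalization, smFISH counting, reporter assays), each printing
the numbers it computes and what they mean.

A thin CLI wraps the library: `granulekit simulate <kind>` writes synthetic
scenes with ground truth, and `granulekit {frap,granules,tracks,coloc,
spots,reporter}` run the analyses on TIFF/CSV/JSON inputs, each run leaving
a `manifest.json` (resolved config, seed, version) for reproducibility.

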