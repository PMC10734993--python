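# Methods

This note records the models, numerical choices, and validation logic
behind rhizotrack, in the order data flows through the pipeline.

## Synthetic series: what the simulator emulates

The simulator stands in for a gantry-robot acquisition of one root per
vessel in clear gel.  Each frame is a float image in [0, 1]:

- **Root.** A dark curve of constant width (default 7 px at intensity
  0.25) whose centerline follows a configurable path — straight (vertical),
  circular arc of radius `arc_radius`, or sinusoid — parameterized by arc
  length.  Arc-length parameterization is what enforces *tip-extension
  growth*: the frame-i path is an exact prefix of the frame-i+1 path, so
  centerlines are comparable by arc length from the base, as in a real
  root where mature tissue is stationary and only the tip elongates.
  Length at frame i is exactly `L0 + i·v` (discretization < 0.5 px).
- **Background.** Gel at intensity 0.65 plus a linear illumination
  gradient across columns (0.0005 intensity/px) plus i.i.d. Gaussian pixel
  noise (sigma 0.02).  Root and label pixels are noise-free; they are much
  darker than any plausible noise excursion anyway, and keeping them exact
  makes noiseless renders strictly two-valued, which several tests rely on.
- **Jitter.** A per-frame integer translation drawn uniformly from
  [−jitter_max, +jitter_max]² (default 4, i.e. a few pixels of residual
  mechanical slop).  Frame 0 has zero jitter by convention — the camera
  homes at series start — so the recorded jitters are exactly the shifts a
  frame-0-referenced registration must recover.  The whole scene,
  container label included, moves with the jitter; the label is a physical
  object in the scene, and its static high-contrast texture is precisely
  what anchors registration.
- **Label.** A square matrix code (below) composited into the top-right
  corner, clear of the root, mirroring a printed label on the vessel.

Defaults describe the reference study condition used throughout the tests:
50 frames at a 15-minute interval, initial length 100 px, growth 4
px/frame.  The simulator makes no attempt to match the optics or pixel
scale of any particular real rig: no lens distortion, no gel texture
beyond i.i.d. noise, no root width variation, no branching, single root
per vessel.  Passing tests therefore demonstrate correctness of the
*algorithms* under a controlled error model, not robustness to every
failure mode of real imagery (uneven lighting and condensation being the
usual offenders).

Determinism: one `numpy` generator seeded from `config.seed` drives all
randomness (jitters first, then per-frame noise), so identical config +
seed reproduces every output byte-for-byte.

## Container labels

Frames are demultiplexed by a compact matrix-code symbology designed for
this axis-aligned, known-scale setting: a 13×13 grid of black/white data
modules carrying `length byte + ASCII payload + CRC-16/CCITT` (capacity 18
bytes), surrounded by a white quiet zone and a solid black finder frame.
The decoder searches the image for hollow dark squares with a light inner
ring, samples the module grid inside, and accepts a payload only if the
CRC validates (all four 90° rotations are tried).  The CRC makes chance
acceptance of noise or root structure vanishingly unlikely (~4/65536 per
candidate region), which is what the corrupted-label tests exercise.  With
several valid labels in view, the largest bounding box wins and a warning
is logged.  Perspective distortion, rotation beyond 90° steps, and other
barcode symbologies are out of scope.

## Registration

Transform family is translation-only, integer-valued: the physical error
is positional jitter of a camera on rails, not rotation or scale, and
integer shifts make recovery assertable exactly.  The shift maximizes the
circular cross-correlation of the mean-subtracted images, computed by FFT,
with the argmax search restricted to a ±`max_shift` window (default 20 px;
the estimate is a true bounded argmax, not an unconstrained peak).
Confidence is the normalized correlation peak in [0, 1]; constant images
yield zero shift at zero confidence with a warning.  Every frame registers
to frame 0 — not the previous frame — so errors do not accumulate over
month-long series.  Vacated border pixels after translation are filled
with the frame median (a robust background estimate).  A static
sub-rectangle can be supplied for estimation if a growing root (or
anything else non-static) occupies much of the frame; with the default
full-frame estimation the label's texture dominates and recovery on
synthetic series is exact.

## Segmentation

Inside a user-chosen ROI, a global Otsu threshold separates root from gel.
Polarity `auto` takes the minority class as root (a root occupies a small
fraction of a sensible ROI).  Cleanup: morphological closing (disk, radius
1), hole filling, and retention of the largest 8-connected component if it
reaches `min_area` (64 px²) — the single-root counterpart of "only the
root of interest".  Otsu always returns *some* threshold, so a bimodality
guard rejects root-free images: the between-class mean separation must
exceed `min_separation` (default 4) times the pooled within-class spread.
Splitting a single Gaussian yields a ratio of about 2.7; a root/gel
boundary at the default contrast sits near 20.  Adaptive thresholding and
subpixel boundary localization are deliberately not implemented; the
global threshold inside a tight ROI is the simplest defensible default.

## Centerline extraction

The mask is thinned to a 1-px skeleton (topology-preserving thinning).
The centerline is the longest geodesic path between degree-1 endpoints of
the skeleton's 8-connected adjacency graph (edge weights 1 and √2),
computed by Dijkstra from each endpoint; shorter side branches — thinning
artifacts on a single unbranched root — are discarded.  A cycle-only
skeleton (no endpoints) is an error.  Orientation: the endpoint nearest
the `base_hint` side (default "top": the plant sits atop the gel and the
root grows down) becomes the base; from the second frame of a series the
base is instead the endpoint nearest the previous frame's base, so a
curling tip cannot flip the orientation mid-series.

**Endpoint retraction correction.**  Thinning retracts the skeleton's ends
roughly one half-width short of the true tip of a capped tube, a
systematic negative length bias (≈3 px at width 7 — 3% of a 100 px root).
For a tube of half-width h the mask's Euclidean distance transform along
the true centerline holds at ≈h until the true endpoint and decays
linearly past it, so each path end is extended along its local tangent in
0.25 px steps while the bilinearly-sampled distance transform stays above
h − 0.5 (h estimated as the median distance-transform value along the
path).  On synthetic capsules this recovers the true endpoints to well
under a pixel; it assumes the root ends inside the ROI with a rounded cap,
and is switchable off (`tip_correction=False`) for roots truncated by the
crop.

## Spline smoothing and curvature

Each coordinate is fit as a function of arc length with a cubic *penalized*
smoothing spline (`scipy.interpolate.make_smoothing_spline`, knots at
every sample) minimizing `Σ residual² + λ ∫ (g'')²`, with
`λ = smoothing × 50` (default `smoothing = 1`).  The penalty acts as a
low-pass filter in arc length with cutoff ≈ λ^(1/4) ≈ 2.7 px: long enough
to damp pixel-lattice stair-stepping, far below the tens-of-pixels scale
of real root bends, so curvature passes through essentially unbiased
(quarter-circle radius 50 px is recovered within ~4%, radius ≥ 100 px
within well under 1%, on sampled paths).  A residual-budget spline
(FITPACK-style `smoothfactor`) was rejected: on smooth arcs it collapses
to a near-single polynomial that is positionally accurate to a fraction of
a pixel yet biases curvature by ~8%.  `smoothing = 0` interpolates;
increasing `smoothing` monotonically reduces curvature energy ∫κ²ds
(asserted in the tests).  The smoothed curve is resampled at uniform
Δs = 1 px; curvature is reported unsigned and the radius capped at
R_cap = 10⁴ px so straight segments stay finite in the kymograph.  Note
that curvature *from image-derived skeletons* carries quantization noise
well above the few-percent level at radii ≳ width²; the kymograph of real
or rendered series is a qualitative map, while quantitative radius
recovery is validated on sampled centerlines.

## Kinetics

Lengths are smoothed with a centered running average (default window 5
frames — enough to suppress ±1 px segmentation jitter at a 15-minute
cadence without masking hour-scale dynamics) before differentiating;
growth rate is the central difference of the smoothed lengths over time,
one-sided at the series ends.  At the series boundaries the averaging
window is clipped to the available frames (so `[0,3,6,9,12]` at window 3
smooths to `[1.5,3,6,9,10.5]`); for ramp-like series this biases the
boundary values, so summary statistics of the rate (mean, CV) use only
frames whose window and central difference are fully supported.  Frames
that fail segmentation or path extraction are flagged missing and excluded
from the windows — never interpolated — and more than half a series
failing aborts with a per-frame diagnostic.  The kymograph averages R(s)
in arc-length bins of Δs_bin = 5 px from the base; cells beyond a frame's
tip are empty.  Pixels are the canonical unit (the rigs this emulates
report no calibrated scale); an optional `px_per_mm` adds mm / mm·h⁻¹
columns to the report.

## Pipeline and determinism

`run` executes sort → stabilize → track per container from one JSON config
(CLI flags override), writing a run log with version, config echo,
per-stage counts, and wall time.  Sorting copies (never moves) raw frames,
conserves counts (input = sorted + unsorted + skipped-with-reason), and is
idempotent.  All analysis outputs are deterministic functions of the input
frames and config; the test suite asserts byte-identical CSVs across
repeat runs.  Video encoding is delegated to external encoders — the
stabilized, ordered frame sequence on disk is the interface.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use 50-frame series at
400×256 px (plus 9-container × 10-frame sorting runs and a 2-container ×
50-frame end-to-end run), chosen as the smallest sizes at which every
claim is exercised at full fidelity — longest-series effects (drift-free
registration against frame 0), boundary-window behavior, and multi-
container demultiplexing all appear at these scales.
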