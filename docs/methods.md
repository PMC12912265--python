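# Methods

This note documents the models, conventions and numerical choices behind
each `yolkflow` stage, what the synthetic generator does and does not
emulate, and the known limitations.

## Conventions

Images are row-major with the origin at the top-left; the row index
increases downward. Analysis movies are assumed pre-oriented with the
EVL–YSL margin at the top, so the animal ("up") direction is decreasing
row index. Vector angles are `atan2(-dy, dx)` in degrees, making up 90°.

All physical-unit conversions live in `yolkflow.units` and are reached
through `CalibratedStack` accessor methods; no analysis module multiplies
by `pixel_size` or `frame_interval` directly (an audit test enforces
this). TIFF metadata is treated as untrusted: calibration always comes
from explicit arguments, with a warning when a stored sidecar disagrees.
Intensities are converted to floating point on load and never rescaled,
preserving comparability between stacks acquired with matched settings.

## PIV flow estimation

Each interrogation window (default edge 14.8 µm, converted to pixels per
run and rounded to the nearest even integer; minimum 8 px) in frame *t*
is compared to the window ± `search_margin_px` (default 8) region of
frame *t+1* by mean-subtracted normalized cross-correlation
(`skimage.feature.match_template`). The displacement is the correlation
argmax; with `subpixel` on, each axis is refined by three-point Gaussian
(log-parabolic) interpolation, falling back to parabolic interpolation
when a neighbour is non-positive. Windows are tiled with 50% overlap by
default and inset by the search margin so every window has a full search
region; windows with zero variance yield invalid vectors with s2n 0.

Vector quality is the ratio of the primary correlation peak to the
secondary peak (the maximum outside a 3×3 exclusion zone around the
primary). Filtering keeps vectors with s2n above 1.0 and speed at most
1.0 µm/min; the threshold is a signal-to-noise *ratio* — a correlation
coefficient itself cannot exceed 1, so a unit threshold is only
meaningful on the peak ratio, the standard spurious-vector criterion in
open PIV implementations. Both values are configurable. Filtering only
flips validity flags; raw values are retained, and all summaries use
valid vectors only.

Vectors are pooled across all frame pairs of a movie before the
quadrant/rose summary. Quadrants are half-open 90° sectors centred on
the axes (right [−45°, 45°), up [45°, 135°), left [135°, 225°), down
[225°, 315°)), so boundary angles deterministically join the
counterclockwise sector. The χ² goodness-of-fit test on quadrant counts
uses Σ(O−E)²/E with df = k−1 and an upper-tail p-value; the expected
proportions must be supplied explicitly.

Only single-pass frame-to-frame correlation is implemented — no window
deformation, multigrid refinement, ensemble correlation, or optical
flow. Sub-µm/min flows at 0.5 s frame intervals correspond to per-frame
displacements of a few hundredths of a pixel; single-vector estimates at
that scale carry noise of similar magnitude, and reliable speeds come
from pooling many windows and frame pairs. The validation therefore
checks pooled means (and, for direction statistics, uses a locally
coherent patchwork field aligned to the interrogation grid so each
window samples one motion class).

## FRAP

Raw traces are normalized by bleach depth:
N(t) = (F(t) − F_bleach)/(F_pre − F_bleach), with F_pre the mean of the
pre-bleach frames (at least 2 required) and F_bleach the first
post-bleach value. This absorbs incomplete bleaching — common with weak
stimulation on a bright cortex — into the denominator and requires no
whole-cell reference region, the fewest assumptions consistent with
recording only the bleached region. The recovery model is a single
exponential N(t) = m·(1 − e^(−t/τ)), the standard description of
cortical actin turnover; reaction–diffusion (Soumpasis) models and
double normalization against an acquisition-bleaching reference are out
of scope. The fit is `scipy.optimize.curve_fit` with m₀ = last observed
value, τ₀ = time to half of the final observed value, and 1e-8
parameter/function tolerances; non-convergent or τ ≤ 0 fits raise a
`FitError` carrying the initialization. Reported: τ, half-time τ·ln 2,
mobile fraction m, residual RMS. Because the normalization pins its
scale to a single noisy frame, individual noisy-trace τ̂ errors at
σ = 0.02 reach ~10%; ensemble validation bounds the median error (< 15%
at σ = 0.05 over 100 traces) instead of over-promising per-trace
accuracy.

## Ablation recoil

The cut is horizontal (parallel to the margin) and opens along the
animal–vegetal (row) axis. A strip ROI crossing the cut is averaged
across its short axis to a per-frame profile; the gap is the longest
contiguous run below 50% (configurable) of the median pre-cut profile
level, with both bounding threshold crossings located by linear
interpolation for sub-pixel width. `cut_index` names the first post-cut
frame; earlier frames supply the baseline. The initial recoil velocity
is the OLS slope of width vs time over the first `fit_frames` (default
5) post-cut points — the noise-robust generalization of a difference
quotient, reducing to it at 2 frames. Because w(t) saturates, any
finite window underestimates w_inf/τ: the bias is ~5% at a window of
0.1·τ and ~12% at 0.25·τ, so the default validation uses dt chosen to
keep the window at 0.1·τ. Viscoelastic (Kelvin–Voigt) recoil fitting is
out of scope, as are vertical cuts.

## Intensity series and accumulation

`intensity_series` reports the mean ROI intensity per frame with three
normalization modes: none; first-frame (divide the series by its frame-0
value — the accumulation convention); and reference-region (divide each
frame's ROI mean by the same frame's reference-ROI mean, e.g. each
embryo's blastoderm, which cancels global per-frame intensity changes
such as photobleaching). `accumulation_slope` is the OLS slope of a
first-frame-normalized series against time in minutes, with its standard
error; unnormalized input is rejected.

## Puncta counting

Images (or a max/sum projection of a sub-stack; projection is the
default to avoid double-counting a vesicle spanning slices) are
binarized at either a fixed threshold (emulating manual thresholding
until only vesicles remain masked) or Otsu's method (the reproducible
automatic default). Components are 8-connected; area is pixel count ×
pixel_size², and a component is in-band when its area lies in the closed
interval [0.2, 2] µm² by default. The band is interpreted as *area* — the
size semantics of the standard particle-analysis tools — though it is
fully parameterized, since a diameter reading would also be defensible.
All components are recorded with an in-band flag; the threshold used is
part of the result.

## Comet tracking

Comets are local maxima above a minimum intensity with non-maximum
suppression, refined per axis by three-point Gaussian interpolation
around the peak (exact for a Gaussian spot) with a 5×5 centre-of-mass
fallback; a truncated centre-of-mass window alone biases wide spots
toward the integer peak, which is why interpolation is the primary
refinement. Linking is greedy: candidate links between consecutive
frames are taken in order of increasing distance, links beyond
`max_displacement_px` are forbidden, unmatched detections start new
tracks, and tracks shorter than `min_track_length` are dropped. There is
no gap closing or merge/split handling — for well-separated comets the
greedy assignment coincides with the globally optimal one (verified
against brute-force enumeration on ≤3-comet instances), and comet speed
is insensitive to the linker in that regime. Per-track speed is summed
step length × pixel_size / (n_steps × frame_interval); the movie mean is
the unweighted mean over tracks.

## Morphometry

Circularity is 4πA/P² with A the foreground pixel count and P the arc
length of the marching-squares silhouette contour smoothed by a circular
moving average whose window grows with contour length (≈ P/80). A fixed
smoothing window leaves a constant staircase residual that does not
vanish with resolution; the scaled window makes the estimate convergent
(circle error < 0.1% at r = 100 px) while respecting sub-pixel boundary
placement. Values slightly above 1 can occur from discretization and are
returned uncapped. The mask must contain exactly one component of at
least 100 px.

Epiboly progression projects the margin landmark onto the
animal-pole-to-vegetal-pole axis and reports the projection parameter;
values outside [0, 1] by more than 0.02 are errors, smaller excursions
are clipped. Landmarks are supplied manually (annotation files) or taken
from the synthetic generator — automatic segmentation of stained margins
is out of scope. `normalize_to_reference` divides measurements by the
arithmetic mean of the same trial's wild-type values.

## Group statistics

Welch's t uses the explicit unequal-variance statistic and
Welch–Satterthwaite df (cross-checked against scipy in tests). The
Mann–Whitney U test is exact by enumeration of all label assignments
when n_a + n_b ≤ 12 with no ties (without ties the pooled ranks are
1..n, making enumeration combinatorial), otherwise a normal
approximation with tie-corrected variance and continuity correction.
Default tails: Welch two-tailed, Mann–Whitney two-tailed, χ² upper-tail;
tails are recorded verbatim in every result and p-values are never
truncated. No multiple-testing correction is applied.

## Synthetic data

The generator produces kinematic ground truth only — no actomyosin
mechanics, membrane tension or vesicle biogenesis is simulated. Noise
follows the standard fluorescence-camera model: Poisson shot noise on
the noiseless image scaled to a stated photon budget, then additive
Gaussian read noise; both optional. Spots are rendered analytically
(Gaussian evaluated at pixel centres at sub-pixel positions), never by
integer-shift resampling, so the texture carries genuine sub-pixel
motion and does not flatter the correlator. Each artifact uses a single
RNG seeded from its configuration; a fixed seed fixes every pixel.

Flow stacks advect puncta on a torus (positions wrap, and spots near an
edge render their periodic copies) so density is stationary. The default
texture density of 0.5 puncta/µm² gives the dense, near-continuous
cortex appearance; frame interval defaults to 0.5 s and programmed
speeds stay ≲1 µm/min, the regime of cortical actin flow. The mixture
scenario assigns one direction class per spatial block (default block =
one interrogation window, offset-aligned to the PIV grid) — a locally
coherent patchwork rather than interpenetrating populations, since
windowed correlation reports the dominant local motion and cannot
resolve superimposed opposing flows within one window.

What passing these validations does *not* show: robustness to uneven
illumination, focus drift, anisotropic PSFs, stage jitter, or textures
whose statistics change over time — real movies have all of these. The
synthetic conditions state their own noise levels; they are not claims
about any particular acquisition.

## Validation problem sizes

The test suite and the acceptance script use deliberately modest problem
sizes chosen to exercise every code path at full fidelity: 512×512
stacks for integer-shift exactness, 300×300 × 12 frames for noisy flow
recovery, a 1400×1400 two-frame patchwork (~530 windows) for direction
statistics, 100-trace FRAP ensembles, 20-seed puncta scenarios, and
2000-replicate null calibrations for the hypothesis tests.
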