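# Methods

`quadmap` analyses — and simulates, with exact ground truth — interleaved
whole-heart recordings of a cAMP FRET biosensor (CFP donor / YFP acceptor)
together with high-speed optical mapping of transmembrane potential (Vm)
and intracellular Ca²⁺. This note records the models, the defaults and
their rationale, the numerical choices, and what the synthetic data do and
do not establish.

## Acquisition model

The instrument interleaves two modalities to avoid spectral crosstalk
between YFP emission and the green excitation of the mapping dyes: one
CFP/YFP frame pair (100 ms exposure) every 10 s, each immediately followed
by a 2 s Vm/Ca burst sampled at 1 kHz. `AcquisitionSchedule` encodes this
timing; each burst is paired with the immediately preceding FRET frame, so
an analysis "slot" carries one ΔFRET value and one APD₈₀ / CaTD₅₀ /
heart-rate triplet. Reference camera geometry: the FRET camera images
7.24 mm × 14.5 mm onto 1024 × 2048 px (≈7 µm/px); the mapping cameras image
10 mm × 10 mm onto 100 × 100 px (100 µm/px).

## FRET ratiometry

FRET is computed per pixel as R = CFP/YFP and normalised to the
pre-stimulus baseline, ΔFRET = R/R₀, which cancels gain, illumination and
curvature differences. Choices the convention leaves open:

- **R₀** is the per-pixel *mean* of R over a configurable pre-stimulus
  frame window (reduces to a single frame when the window has length 1).
  Averaging is robust to frame noise.
- **ROI order**: the ratio is formed per pixel first and then averaged over
  the ROI ("ratio of means" vs "mean of ratios" — we use the latter, i.e.
  pixel-wise ratios, matching per-pixel mapping practice).
- **YFP floor**: pixels whose YFP ever falls to the floor (default 0 on
  background-subtracted counts; 5× the camera offset is a reasonable
  setting otherwise) are dropped from the mask to avoid ratio blow-up.
- **Bolus metrics**: Max R/R₀ is the post-baseline maximum (earliest frame
  on ties); the 50% decay time is the first post-peak, linearly
  interpolated crossing of the level halfway between the peak and the
  baseline of 1.0 (not halfway to any post-drug plateau), minus the peak
  time. Responses smaller than 1% above baseline leave the metrics
  undefined rather than raising.

Split-detector registration (CFP vs YFP half-images) maximises the
normalised cross-correlation of time-averaged frames by exhaustive integer
search within ±`max_shift`, ties resolved to the smallest |dy|+|dx| then
row-major order.

## Electrophysiology analysis

Bursts are processed per the standard optical-mapping chain:

1. **Spatial filter**: 3 × 3 Gaussian, σ = 1 px, normalised to sum 1.
   The kernel is the outer product of exp(−{1,0,1}/2) / normaliser.
2. **Polarity**: voltage dyes of the RH237 family darken on
   depolarisation, so Vm defaults to polarity −1 (Ca to +1); traces are
   sign-normalised before any detection.
3. **Baseline drift**: top-hat correction — subtract the grey morphological
   opening (erosion then dilation, flat structuring element). The element
   length defaults to 1.5 × the median beat interval, estimated by a first
   pass with a generous window; it must exceed the beat period or beats
   would be eroded. Near the trace ends the truncated element leaves a
   small residual — an inherent boundary effect.
4. **Beats**: peaks of the forward-difference derivative above 0.5 × its
   maximum, separated by ≥ 50 ms; heart rate is 60000 / mean
   inter-activation interval (ms) when ≥ 2 beats exist.
5. **Activation**: time of maximum upstroke derivative. Derivative samples
   within 1% of the maximum are treated as ties and resolved to the
   *earliest* sample: a linear upstroke has an exactly constant derivative,
   and the spatial filter perturbs that tie by epsilon toward the rise end,
   which would otherwise bias activation late by most of the rise time.
   Optional parabolic sub-sample refinement fits the three derivative
   samples around the maximum (with the half-sample shift of forward
   differences). It is off in the scalar `activation_time` but **on** in
   `activation_map`: at 1 kHz, 0.1 mm pixels and ~0.35 mm/ms conduction, a
   whole disk of pixels around the focal source ties at the same activation
   sample, and the row-major tie-break would misplace the earliest site;
   refinement restores exact pacemaker localisation. Constant offsets
   cancel in the map, which is reported relative to its minimum.
6. **Durations**: APD₈₀ / CaTD₅₀ run from activation to the first
   post-peak, linearly interpolated crossing of peak − level × amplitude
   (level 0.8 / 0.5). Amplitude references the diastolic baseline, the mean
   of the 10 ms preceding each pixel's upstroke within the beat. Two
   numerical refinements: the upstroke foot is back-extrapolated to
   sub-sample precision (act − d[act−1]/d[act], exact for a linear rise),
   and the repolarisation crossing requires two consecutive sub-threshold
   samples (identical on monotone noise-free decays, suppresses
   single-sample noise dips). Without these, filter-plus-discretisation
   effects leave zero-noise CaTD₅₀ errors slightly above one sample and
   noise produces an early-crossing bias.
7. **Averaging**: the first 10 complete beats of each burst (all available
   when fewer), per pixel; pixels with no valid beat are NaN.

## Synthetic data generator

The generator is the package's oracle: every analysis target is known
exactly.

- **Waveforms** are linear-rise / exponential-shoulder templates calibrated
  so the duration definitions hold by construction: the action potential
  (2 ms upstroke) decays with τ = (APD₈₀ − rise)/ln 5, crossing 20% of the
  unit amplitude exactly APD₈₀ ms after the maximum-derivative time; the
  calcium transient (5 ms rise) uses τ = (CaTD₅₀ − rise)/ln 2 for the 50%
  crossing. Past a knee the decay blends linearly to exactly zero so the
  diastolic baseline is clean before the next beat.
- **Geometry**: elliptical masks with labelled regions. The anterior
  ventricular preset carries RV-base / LV-apex / LA ROIs and a focal
  breakthrough near the base; the posterior atrial preset places the
  focal source inside an intercaval SAN patch. Activation delays are
  Euclidean distance / conduction velocity (0.35 mm/ms default) — on these
  convex masks Euclidean and geodesic distances coincide.
- **Regional baselines**: APD₈₀ 55/45/50 ms and CaTD₅₀ 45/35/40 ms for
  base/apex/elsewhere — a base-to-apex repolarisation gradient of the size
  seen in murine hearts.
- **Response curves** are piecewise-linear time courses. The
  norepinephrine preset encodes the reported kinetics: ΔFRET rises to its
  peak at 40 s and returns to baseline by 120 s; APD is biphasic
  (maximum prolongation at ~40 s, back to baseline by 60 s); CaTD falls
  monotonically (to 0.85× by 60 s); heart rate rises 300 → 500 bpm with
  the cAMP time course. The tyramine preset shifts the strongest cAMP
  response to the left atrium; the acetylcholine preset is a reversible
  ΔFRET *reduction* (values ≤ 1). Peak amplitudes (ΔFRET 1.2 by default)
  and the transduction below are simulator conventions, not measured
  values.
- **Transduction**: CFP = gain·ΔF^a, YFP = gain·ΔF^(−b) (a = b = 0.5), so
  the donor rises and the acceptor falls as cAMP rises and, whenever
  a + b = 1, the recovered ratio equals the true ΔFRET *exactly* — the
  property the 1e-6 oracle-equivalence tests rely on. A linear
  transduction cannot satisfy that identity for all amplitudes, which is
  why the power form was chosen. FRET-channel counts are assumed
  dark-offset-subtracted (offset 0); the Vm/Ca channels keep an offset,
  removed downstream by baseline correction.
- **Detection chain**: radial cosine vignetting (1 at the mask centroid to
  1 − strength at its edge, emulating curvature-driven illumination
  falloff; it divides out of the ratio), linear spectral bleed-through
  mixing applied to the count-scale signals before noise (diagonal 1,
  off-diagonal ≤ 0.5; default Ca→Vm leak 0), additive Gaussian noise only
  (photon-shot statistics are not modelled — no absolute photon counts are
  available to calibrate them), and an optional ±1 px per-frame motion
  jitter toggle. Dye-loading flags allow rendering a heart with only the
  Ca dye, the configuration in which bleed-through is measurable as the
  slope of the Vm channel on the Ca channel.
- **Determinism**: a single `numpy` Generator seeded from the `seed`
  argument drives all randomness; identical configs and seeds give
  bit-identical stacks.

### What the synthetic data do not emulate

Real motion artifacts (only rigid jitter), photon-shot and camera read
noise statistics, fluorophore photobleaching, spatially varying sensor
expression, restitution (APD is independent of rate), 3-D geometry and
depth-averaged signals, and pharmacokinetics (drugs are response-curve
presets). Passing the recovery tests therefore shows the *analysis chain*
is correct and well-conditioned at realistic SNR, not that it is robust to
every artifact of real recordings.

## Crosstalk validation

ΔFRET traces acquired under different dye loadings are compared with the
two-sample Kolmogorov–Smirnov test (asymptotic p-values; exact small-n
enumeration is out of scope). Default mode compares the raw value
distributions; a `paired_difference` mode instead tests the symmetry of
time-paired differences about zero by a two-sample KS of d against −d.
Results are labelled with the mode. Bleed-through is the least-squares
slope of the (baseline-corrected, time-aligned) contaminated channel on
the source channel, clipped to [0, 1].

## Coregistration and statistics

Fiducial point pairs fit a 4-parameter similarity transform
(least-squares, Umeyama) between camera grids — the cameras share optics
and differ mainly in scale and offset, so a full affine is unnecessary and
would demand more fiducials (≥ 2 non-coincident pairs suffice here). ROIs
rasterise onto the target grid by pixel-centre inclusion in the convex
hull of the transformed source-pixel corners (0-based, row-major
coordinates throughout). Regional summaries are mean ± SEM (sample SD,
n−1 denominator, over hearts; SEM undefined at N = 1); regional contrasts
use classical paired two-tailed t-tests with differences d = a − b and no
multiple-testing correction, matching the per-comparison reporting
convention.

## Problem sizes and reproduction

Tests run the full chain on 48 × 48 grids (10–120 s schedules); the
reproduction script `scripts/acceptance.py` uses the 64 × 64 default
norepinephrine run — bursts every 10 s for 120 s, noise SD 5% of the
signal amplitude — and reports the camera pixel pitches and the burst
times at which the whole-mask mean APD₈₀ peaks and first returns to
within 2% of its pre-stimulus baseline. These sizes keep a complete run
in the one-minute range on a single CPU while leaving dozens of pixels
across every labelled region.

## Known limitations

- Duration maps inherit a small noise-dependent bias (the morphological
  opening under-sits noisy baselines, compressing the measured amplitude);
  at 5% amplitude noise the median APD₈₀ error is ~0.5 ms.
- Activation maps assume a single focal wavefront per beat; re-entry and
  collision patterns are out of scope, as are conduction-velocity vector
  fields and alternans detection.
- The KS p-values are asymptotic and mildly conservative below n ≈ 50.
- `map_roi` uses the convex hull of the transformed ROI, which over-covers
  strongly non-convex ROIs.
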