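# Methods

This note records the models, defaults, numerical choices and known
limitations behind `crestvib`, at the level of detail a maintainer or a
careful user needs.  Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Oscillator model

The fundamental bending mode of a clamped feather crest is modelled as a
single-degree-of-freedom damped harmonic oscillator.  Two descriptions are
used, deliberately kept distinct:

**Transfer mode** defines the response directly through the empirical
Lorentzian resonance form

    H(f_d) = (f_r/f_d) / [ (f_r/f_d − f_d/f_r)² + (Δf/f_r)² ],

with `Q = f_r/Δf`, `H(f_r) = Q²` and `H(0) = 0`.  A synthetic sweep built
this way makes the estimation pipeline's fit model exact by construction,
so parameter-recovery tests are well-posed: any residual error is
attributable to the estimator, not to model mismatch.  A fitted
multiplicative `scale` is added because a measured amplitude ratio carries
an unknown static gain; synthetic data use `scale = 1`.

**ODE mode** integrates the physical second-order system
`x'' + 2ζω_n x' + ω_n² x = ω_n² u(t)` with damping ratio `ζ = 1/(2Q)`.  The
undamped frequency is placed at `f_n = f_r/√(1 − 1/(2Q²))` so that the
forced-response amplitude peak of the physical system sits exactly at
`f_r` — this keeps `f_r` meaning the same thing in both modes.  Free decay
then oscillates at `f_n√(1 − ζ²)` with amplitude e-folding time
`τ = Q/(π f_n)`.  The empirical Lorentzian's maximum is *not* exactly at
`f_r` (about 0.33% below it at `Q = 6.2`); keeping the two synthesis modes
separate is what lets each test state an unambiguous oracle.

Integration uses a first-order-hold discretization of the state-space
system at ≥ 2 kHz (forcing linearly upsampled if supplied coarser),
followed by FIR anti-aliased decimation back to the observation rate.  This
emulates camera sampling while avoiding integrator aliasing.

## Stimulus protocols (synthetic-data defaults)

The generator's defaults are the study conditions themselves:

| protocol | default | notes |
| --- | --- | --- |
| frequency sweep | 0→80 Hz linear chirp at 1.33 Hz/s, 240 Hz sampling | ~60 s per trial |
| impulse (vortex) | Gaussian pulse, σ = 5 ms, simulated at 2.4 kHz | single impact, ring-down follows |
| rattle train | repetition 26.7 / 25.3 / 24.6 Hz; 8 ms Gaussian-windowed noise burst | see below |
| white-noise control | equal rms to the rattle train, exact scaling | audio-band flat |
| wing-shaking | 4.95 Hz sinusoid, 60 s | robot-drive frequency |

The rattle train repeats **one** burst realization periodically: rattle
notes are temporally coherent, so the train is strictly periodic and its
spectrum is a line comb at harmonics of the repetition rate.  (An early
variant drew an independent noise burst per period; that train has *no*
spectral line at the repetition rate — its periodicity lives only in the
envelope — and a crest driven by it responds at its own resonance instead
of the rattle rate, which is not what crests do under real playback.)  The
burst carrier is noise low-passed to 500 Hz by default: broadband relative
to the ~26 Hz rate, like a mechanical click, but not white to the Nyquist
of whatever simulation rate is in use.

For the white-noise control comparison, both stimuli are synthesized at
44.1 kHz, because the experimental control was a flat-spectrum audio file
played through the same chain at equal rms.  Band-limiting the same rms
into a narrower simulation band would inflate the noise's spectral density
near the rattle rate by the bandwidth ratio and with it the control power
ratio; at audio bandwidth the simulated ratio comes out well under the
few-percent level observed on real crests (the acceptance script computes
it).

Trial-to-trial measurement noise is multiplicative (default 5% per sample)
for sweep trials — video amplitude extraction errors scale with signal — and
additive for the small-signal protocols.  Every stochastic operation takes
an explicit seed (package default 20181128) and is bit-reproducible.

## Video tracking

Per region of interest and frame: contrast-stretch to the full intensity
range, threshold (Otsu's between-class-variance criterion by default, or a
fixed value), then take the intensity-weighted centroid of above-threshold
pixels using **baseline-subtracted** weights `max(I − thr, 0)`.  The
subtraction makes the weight decay continuously to zero at the threshold
boundary; with a hard cut, the truncated tail of a blob straddling a pixel
edge biases the centroid by ~0.06 px, with subtraction the error stays
below 0.05 px for any sub-pixel position (property-tested).  Contrast
stretching makes the result invariant to global affine intensity changes.

Coordinates are image-style: origin top-left, x right, y down, 0-based,
centroids at pixel centers.  Frames with no above-threshold pixels are
flagged missing, never dropped; gaps of at most 3 consecutive frames may be
linearly interpolated, longer gaps are an error, and an ROI missing more
than 5% of frames fails the whole track.  Lens distortion and perspective
are assumed corrected/negligible upstream.  "Mean position" is implemented
as the intensity-weighted centroid; a binary-mask centroid is an equally
defensible reading of the same words, and the choice is recorded here
rather than asserted as the original intent.

## Sweep analysis

Both tracked series (drive and response) are analysed with Hann-windowed
short-time FFTs: 1.0 s window, 75% overlap, 8× zero-padding for sub-bin
peak placement.  Per slice, the drive frequency `f_d` is the drive
spectrum's argmax, `A_d` the drive magnitude there and `A` the response
magnitude at the same bin; `H_raw = A/A_d` on the resulting grid (duplicate
grid points averaged), then smoothed with a cubic Savitzky–Golay filter
whose span is the odd point count closest to 1.3 Hz.  The window length is
a compromise: for a 1.33 Hz/s sweep the chirp's intrinsic time–frequency
localization is ~0.87 s, so ~1 s windows are near-optimal and the effective
spectral smearing is ~1 Hz either way.

That smearing is the pipeline's known bias: it slightly broadens the peak,
so fitted `Q` comes back ~0.5–1% low (measured across Q 4–8, noise-free)
while `f_r` is symmetric under the smearing and recovers to ~10⁻⁴
relative.  The recovery tests assert 10⁻³ on `f_r` and 2×10⁻² on `Q`/`Δf`
accordingly; group-mean recovery under 5% trial noise is far inside the
±0.4 Hz / ±0.5 bands the acceptance suite checks.

Peaks are local maxima of the smoothed curve with prominence ≥ 5% of its
global maximum.  Only the dominant peak is fitted (clusters of 2–3 peaks
are reported as `secondary_peaks`; aggregation across peaks is left to the
statistics layer).  The fit is trust-region least squares of
`scale·H(f; f_r, Δf)` against `H_smooth` in a window of
± max(3·Δf⁰, 10 Hz) around the peak, initialized from the peak location and
its measured half-power width, with relative tolerance 10⁻⁸ and ≤ 10⁴ model
evaluations.  A fitted width below 2 grid spacings is rejected as
degenerate.  `Q = f_r/Δf` is a derived property, so the identity holds
exactly in every fit.

## Ring-down analysis

The post-impulse segment starts at the first sample after the absolute
maximum of the mean-removed series (the instant the impulse has fully
loaded the crest).  Initialization: frequency from the segment's
rectangular-window FFT peak (a Hann window would null the decaying burst at
the segment's leading edge; bins below two cycles per segment are
excluded), decay time from a straight-line fit to the log of the Hilbert
envelope, phase from the analytic signal.  The five-parameter decaying
sinusoid is then fitted by nonlinear least squares; fewer than 5 cycles, or
adjusted R² < 0.2 (incoherent input, e.g. pure noise), is a clean failure.

The natural/resonant frequency relation is implemented as printed,
`f_o = f_r√(1 − 1/(2Q²))`, with an explicit `convention="damped_free"`
alternative (`√(1 − 1/(4Q²))`).  The printed direction places `f_o` *below*
`f_r`, whereas for a second-order system the free frequency sits slightly
above the forced peak; the two conventions differ by O(f_r/Q²), about
0.1–0.3 Δf at crest-like parameters, inside the ±0.4 Δf agreement band
either way — the acceptance grid verifies this, and the flag documents the
ambiguity instead of silently resolving it.  (Relatedly: a 13%-in-0.2 s
amplitude decrease sometimes quoted for vortex responses is mutually
inconsistent with `τ = Q/(πf)` at crest-like parameters, which gives ~7%
*remaining*; the package asserts only the exponential-decay arithmetic.)

## Forced-response analysis

Welch averaged periodograms, 50% overlap; 2 s segments (0.5 Hz bins) for
playback responses and 20 s (0.05 Hz) for wing-shaking, matching the
resolutions of the corresponding experiments.  Hann window for responses;
rectangular reserved for amplitude-preservation checks on constructed
stimuli (Parseval within 1% is property-tested).  `power` holds per-bin
power so band sums approximate variance directly.  The dominant peak in a
band is the maximum bin; exact ties resolve to the lowest frequency and are
flagged.  Band-power ratios default to ±0.5 Hz (one bin) around the nominal
rate and are invariant to common amplitude calibration.  Note a line at
26.7 Hz lands in the 26.5 Hz bin of a 0.5 Hz grid; peak frequencies are
reported at bin centers, so agreement is always "within one bin".

## Statistics

The mixed model is a Gaussian random-intercept model per crest, fitted by
REML (reported components) or ML (AICc comparisons) through closed-form
compound-symmetry algebra per group and quasi-Newton optimization over
log-variances, with an optional Nelder–Mead polish that brings balanced
designs to within 10⁻⁶ of the analytic method-of-moments solution
(oracle-tested; the homoskedastic case is also cross-checked against an
independent library implementation).  The heteroskedastic variant profiles
one residual-variance multiplier per crest (first fixed at 1); with very
few trials per crest these multipliers are weakly identified, so the
homoskedastic model is the default.  An estimated among-crest variance
below 10⁻⁸ of the total is reported as exactly 0 (boundary).

Adjusted repeatability is `σ²_id / (σ²_id + σ̄²_res)` with `σ̄²_res` the
mean per-crest residual variance; its CI is a seeded parametric bootstrap
(resimulate from the fitted model, refit, percentile interval; default 1000
draws, bootstrap refits skip the polish for speed).  Marginal R² is
`var(Xβ)/(var(Xβ) + σ²_id + σ̄²_res)` over the observed design rows.  AICc
is `−2ℓ + 2k + 2k(k+1)/(n−k−1)` on ML fits only.  Candidate models carry at
most one morphological covariate alongside sex and orientation, matching
the power constraints of a 15-crest design.

Bending stiffness: points ordered by displacement from the zero-force
onset; the linear window grows until the next point departs from the
current straight-line fit by more than 4× the in-window residual rms (with
a 10⁻⁶ full-scale floor so exact data behave), then the window must reach
adjusted R² ≥ 0.98 to count as linear, and its slope is `k` (N/mm).  The
sequential criterion exists because a global R² floor alone cannot localize
a softening breakpoint — a long linear run keeps R² above 0.98 for several
points past even a hard plateau.

## Synthetic population and what passing tests show

`generate_fixtures` writes a 15-crest population (7 male-like, f_r ≈
26.3 Hz, Q ≈ 6.2; 8 female-like, f_r ≈ 28.1 Hz, Q ≈ 4.8, out-of-plane),
among-crest SD 1.0 Hz in `f_r` and 0.5 in `Q`, within-crest trial SD
0.25 Hz, in-plane trials 2.4 Hz lower, three sweep trials per crest and
orientation, vortex/playback/wing-shaking trials and plateauing bending
curves with k ∈ [0.0022, 0.0054] N/mm.  The spreads are chosen to produce
high but imperfect repeatability, comparable to real crests.

The generator emulates: linear single-mode dynamics, ideal periodic or flat
stimuli, Gaussian noise, and one bright blob per ROI.  It does not emulate
multi-modal feather dynamics, inter-feather coupling, amplitude-dependent
(nonlinear) stiffness, vortex aerodynamics, speaker/room acoustics, image
blur, occlusion, or lens distortion.  Passing tests therefore demonstrate
that the estimators recover known parameters under the study's protocols
and noise levels — not that real crest data are free of those effects.

## Problem sizes

Recovery tests use 20–40 sweeps of the full 60 s protocol; the consistency
grid is 5×5 oscillators; playback simulations are 300 s (44.1 kHz for the
control-ratio comparison, 2.4 kHz otherwise); the repeatability coverage
study runs 30 replicates × 100 bootstrap draws.  These sizes were chosen to
keep the full suite and the acceptance script each in the minutes range on
one CPU while leaving Monte-Carlo noise well below the tolerances tested.
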