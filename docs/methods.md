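# Methods

This note records the models, numerical choices and known limitations
behind `respigate`. Everything quantitative stated here is computed by
the test suite or the analysis scripts; nothing is quoted from external
data.

## The problem

Whole-heart 4D flow MRI acquires for several minutes while the subject
breathes freely; accepting only data from a quiet respiratory window
(end-expiration) reduces motion blur at the cost of scan efficiency. Two
gating signals are in common use: the MRI-native liver–lung navigator
(a pencil-beam measurement of diaphragm position, here 2 Hz, mm) and an
in-bore camera (contact-less, here 20 Hz, arbitrary units). Whether the
two are interchangeable is a question about their *phase* agreement
after binning, not their amplitudes — an arbitrary-unit video signal and
a millimetre displacement cannot be compared directly. This package
implements that comparison chain on synthetic data with known ground
truth.

## Latent breathing model

`gen_breathing_waveform` produces a unit-amplitude quasi-periodic trace
at 100 Hz. Each cycle is a cosine in a warped phase,
`y = (1 − cos 2πφ(t))/2`, with the phase speed piecewise constant:
a common speed inside symmetric "caps" around every trough and peak
(default half-width `cap_s = 0.6 s`, shrunk when cycles are short) and
segment-specific speeds in between, chosen so the peak falls exactly at
`insp_fraction` of the cycle. Cycle lengths are drawn independently with
fractional SD `rate_jitter` (truncated at ±3 SD).

Why the caps: real breathing has rounded extrema (and an approximate
end-expiratory plateau), and — decisively for testability — a waveform
that is locally *symmetric* around its extrema keeps its extrema in
place under the pipeline's 1 s moving average. With a plain asymmetric
raised-cosine (40:60), the smoothing displaces peak and trough by about
0.1 s each and the measured expiration fraction drops from 60% to ~55%;
with the caps the binning chain recovers the generator's
inspiration:expiration split to well within 2 percentage points
(`test_acceptance_tracks_expiration_fraction`).

Defaults (the study conditions): 15 breaths/min, jitter 0.05,
`insp_fraction` 0.4 (a physiologic ~1:1.5 inspiration:expiration ratio),
120 s traces. Sensor stage (`gen_modality_pair`): camera 20 Hz in a.u.,
navigator 2 Hz in mm with per-subject scales spread ~3× across a cohort;
per-sensor additive Gaussian noise, slow sinusoidal baseline drift, and
one-sample-wide outlier spikes at Poisson times (camera only by
default — isolated video glitches survive into amplitude ranges but not
into phase bins). An optional `nav_lag_s` delays the navigator to test
delay recovery.

What the generator does **not** emulate: cough/apnea epochs, breathing
pattern drift (rate changes over minutes), cardiac contamination of the
navigator, or the vendor camera's internal block-matching — only its
output signal is modelled. Passing tests therefore show correctness of
the *analysis chain*, not robustness to every real-world signal
pathology.

## Phase binning

The chain is: rescale to zero median → smooth over 1 s → minimal
same-sign peak distance `floor((60/45 bpm) · fs)` samples → extrema
pass 1 (distance only) → prominence threshold = 0.25 × median
trough→peak amplitude swing of pass 1 → extrema pass 2 (distance +
prominence) → double-extrema correction → bins.

Numerical choices:

* **Smoothing** is a centred moving average; even window lengths get
  half-weight endpoints so the average never carries a half-sample
  delay (a plain 2-sample average at 2 Hz would delay the navigator by
  0.25 s). Edges use shrinking windows.
* **Minimal distance** is floored, not rounded, so the 45 breaths/min
  constraint is never violated at low sampling rates.
* **Prominence** is the standard topographic definition
  (`scipy.signal.find_peaks`); the threshold's "median maxima–minima
  distance" is read as an amplitude quantity (median over consecutive
  minimum→following-maximum swings), since prominence is an amplitude.
* **Double extrema**: among consecutive same-sign extrema the more
  extreme one is kept.
* **Bin mapping** (`mode="segment"`, default): bins 1–40 cover the
  trough→peak segment and 41–100 the peak→trough segment, each linear in
  time, `floor`-quantised, boundary convention "a sample exactly at a
  maximum opens expiration (bin 41)". The accepted fraction of a trace
  therefore equals its expiration *time* fraction — ~60% for physiologic
  breathing — rather than a fixed 60% of wall time. A whole-cycle linear
  mapping is available as `mode="cycle"`.
* Samples before the first and after the last retained extremum are
  rejected (bin 0); partial cycles at the record ends are not
  extrapolated. This costs less than one cycle per trace end.
* **Low-rate traces**: `compute_phase(..., interp_to_fs=20)` linearly
  interpolates the trace to a finer grid before any processing. On the
  native 2 Hz grid the discrete peak search must compare samples up to
  half a sample (250 ms) from the true extremum, and those comparisons
  reach into the asymmetric flanks of the cycle, dragging detected peaks
  systematically late and troughs early by ~50–100 ms. Interpolation
  first makes every effective kernel symmetric; measured navigator lag
  recovery then lands within one 50 ms grid step of the injected lag.
  (Parabolic sub-sample refinement of extrema was tried and rejected:
  the 3-point parabola at 2 Hz spans ±1 s and inherits the asymmetry.)

Robustness, measured: single-sample spikes below 0.25× the cycle
amplitude leave ≥95% of bins unchanged to within one bin (a spike
landing on a flat extremum cap can still nudge the detected trough by
~2 samples, moving nearby bins by up to 3); a slow sinusoidal drift of
half the breathing amplitude changes the accepted-sample set by <5%.

## Phase agreement

Phase series are resampled to a common 20 Hz grid and cross-correlated
(mean-removed, norm-normalised) over lags within ±2000 ms; `C_phase` is
the peak, `d_phase` the lag at the peak (ties → smallest |lag|; positive
= second series lags the first). Bin numbers are correlated as real
values (the sawtooth peaks sharply at the true lag); circular phase
representations were not needed.

Resampling is cliff-aware: nearest-neighbour upsampling of a 2 Hz bin
series puts the per-cycle 100→1 reset half a source sample (250 ms)
before the detected trough, which biased delay estimates by ~−200 ms.
The correlator therefore unwraps the sawtooth (+100 per cycle), pins the
reset to the detected trough time, interpolates linearly onto the target
grid and wraps back. Plain nearest-neighbour remains available
(`resample_phase(..., method="nearest")`).

`mismatch_percent(d, rate) = 100·|d|/(60000/rate)` expresses a delay as
a fraction of the breathing cycle. Amplitude summaries use
linear-interpolation quartiles and the uncapped Tukey whiskers
`W = Q3 ± 1.5·IQR`; cohort range ratios are ratios of cohort means of
`(W_up − W_low)` and of `(max − min)`.

## Phantom and image quality

The phantom is a 4D volume whose mean intensity along z is a logistic
edge `lung + (liver − lung)·expit((z − z0)/w)` — the same functional
family the edge fitter assumes, which makes width recovery a well-posed
test. Motion blur (the ungated condition) averages each frame over
Gaussian z-shifts of the ideal edge (default SD 2 voxels, 25 draws)
before adding noise, widening the effective edge monotonically.

SNR uses the sample SD (ddof = 1) of the lung slice per frame; a
noise-free phantom returns `inf` as a sentinel. LLE fits
`b + a/(1 + exp(−(z − z0)/w))` per time-averaged profile
(initialisation: b = min, a = range, z0 = steepest gradient, w = 2;
bounds w ∈ (0.05, nz]); a fit counts as converged only if the optimiser
succeeds, `a > 0`, and `w` is strictly inside its bounds — a width stuck
at the lower bound (step edge) is a model failure, not a measurement.
Non-converged profiles are excluded, never imputed; if more than half
fail, `compute_lle` raises with the counts. "Width" is the logistic
scale parameter `w`; `width_convention="tangent"` reports `4w`. Profiles
are time-averaged before fitting, matching the time-averaged SNR
treatment; the full ROI z-extent is fitted (whether the designated
liver/lung slices should be excluded is ambiguous; including them
changes nothing on logistic edges). Measured recovery: median width
error ≤ 0.25 voxel over widths {1, 2, 4} × SNR {5, 10, 20}, and ~0.01
voxel at cohort-default noise.

## Statistics

* **RM-ANOVA**, multivariate form: with k = 3 conditions, the k−1
  within-subject difference variables give Hotelling
  `T² = n·d̄ᵀS⁻¹d̄`; `Λ = 1/(1 + T²/(n−1))`,
  `F = T²(n−k+1)/((n−1)(k−1))` on (k−1, n−k+1) df, partial η² = 1 − Λ.
  All-zero differences short-circuit to Λ = 1 (no effect); a singular
  difference covariance with nonzero means raises. The univariate
  sphericity-corrected form is out of scope. Note the df convention:
  for n subjects the multivariate error df is n−k+1, not the univariate
  (k−1)(n−1).
* **Pairwise**: paired t per condition pair, `p_bonf = min(1, 3p)`, CIs
  at Bonferroni-adjusted coverage 1 − α/3; both orderings reported with
  mirrored signs.
* **Krippendorff's α** (ordinal) from the coincidence matrix with
  `δ²(c,k) = (Σ_{g=c..k} n_g − (n_c + n_k)/2)²`; missing entries follow
  the pairable-values rule. Implemented here directly (no suitable
  installed library) and verified against a brute-force pair-enumeration
  oracle to 1e−12.
* **Bland–Altman**: bias ± 1.96 × sample SD of paired differences.
* The cohort cross-correlation hypothesis ("C > 0.5") is a one-sample
  one-sided t-test; degenerate zero-variance samples return 0, 1 or 0.5
  by the sign of the common value.

Type-I calibration of the ANOVA is checked by simulation (1000 null
cohorts, rejection rate within [0.03, 0.07] at α = 0.05).

## Cohort pipeline and problem sizes

`run_cohort_study` simulates 8 subjects (120 s traces), bins both
modalities, measures agreement, scores per-condition phantoms
(10×10×30×3) and runs the statistics; it completes in a few seconds and
is bit-reproducible for a fixed master seed (all per-subject streams are
spawned from it). CAM and NAV differ only by sensor model — sampling
rate, units, noise, outliers — never by gating correctness, so the
expected cohort behaviour is: high phase correlation, no CAM-vs-NAV
difference, and a clear LLE penalty for the ungated condition. With
`accept_range: 1:100` gating is off for every condition (negative
control) and the quality metrics collapse onto each other.

SNR in this phantom is deliberately insensitive to motion blur (the
liver and lung slices sit away from the edge, and blur moves the edge,
not the noise), so the pipeline's SNR ANOVA is a null comparison; the
gating effect is carried by LLE. Emulating the SNR penalty of real
ungated reconstructions would require modelling ghosting artifacts,
which is out of scope.

## Known limitations

* The generator's breathing is stationary; acceptance-fraction accuracy
  degrades at high rates (>20 breaths/min) where the extremum caps
  shrink below the smoothing reach (observed up to ~7 points of
  acceptance error at 20.6 breaths/min in the cohort run).
* Delay recovery resolution is one correlation grid step (50 ms at
  20 Hz), with a residual lean of about −25 ms from the navigator's
  remaining quantisation; injected lags are recovered within ±50 ms.
* The phantom's edge is exactly logistic; LLE accuracy on non-logistic
  real borders will be model-limited.
* Ratings are simulated with a crude disagreement model (single-level
  flips); α values are meaningful as orderings (perfect > high >
  random), not as absolute cohort predictions.
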