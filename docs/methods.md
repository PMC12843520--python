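# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of the `neuroforecast` package: what each stage computes, what
the synthetic study generator does and does not emulate, and which design
decisions were genuinely open.

## Study design being modeled

A laboratory focus group of ~28 subjects watches ~14 pitch videos
(63–112 s each, randomized order) while 20-channel 10–20-montage EEG (19
scalp channels + 1 EOG) is recorded. After each video, subjects rate five
7-point investment-interest items and predict the deal outcome; a separate
large online sample (~497 raters) provides population-level interest per
video; real-world outcomes are the binary deal and the funding amount.
Analyses correlate group-level neural statistics with per-video outcomes,
so the effective sample size for forecasting is the number of videos — a
deliberately small, exploratory design (see Power below).

## Preprocessing

Fixed order: band-pass → epoch → bad channels → EOG regression → baseline.

* **Band-pass 0.3–50 Hz**, zero-phase FIR (Hamming window, forward-
  backward), so no group delay shifts window timestamps relative to video
  onsets. The upper transition band is fixed at 5 Hz so the filter
  actually rejects 50/60 Hz mains noise; the lower transition follows the
  standard 25%-of-edge rule. The EOG channel passes through the same
  filter. The filter family and order were not externally constrained;
  these are this package's documented choices.
* **Epoching**: one epoch per video onset spanning [−0.2 s, duration);
  0-based sample indexing, half-open windows, the onset sample belongs to
  the epoch. Events with insufficient pre-stimulus room are errors.
* **Bad channels**: a channel is flagged when the z-score of its
  log-variance across channels exceeds 4, when its maximum absolute
  correlation with every other scalp channel falls below 0.4, or when it
  is flat. This transparent variance/neighbor-correlation detector stands
  in for consensus-based detectors (RANSAC-style) whose internals would
  otherwise be opaque to testing; flagged channels are replaced by the
  unweighted mean of their 10-20 neighbors (adjacency table shipped as a
  versioned JSON data file). An epoch with all channels bad is
  unrecoverable.
* **Ocular artifacts**: instead of ICA, the EOG channel is regressed out
  of each scalp channel whose EOG-correlation Fisher-z statistic
  (`z = atanh(r)·sqrt(n−3)`) exceeds 1.96 in magnitude — the same two-sided
  threshold commonly used to select ocular components. Channels below
  threshold are untouched; the EOG is dropped afterwards. This removes
  linear blink leakage (tested on blink-injected synthetic data) but not
  nonlinear or saccadic artifacts.
* **Baseline**: per-channel mean over [−0.2, 0) subtracted; idempotent.

No re-referencing is applied; recordings are assumed referenced at
acquisition (linked mastoids in the emulated setup).

## Spectral estimation

* **Welch band power** (whole-video FAA): 2 s Hamming segments, 50%
  overlap — ≥ 0.5 Hz resolution across the alpha band; band edges are
  inclusive. Only post-onset samples enter.
* **Morlet envelopes** (windowed FAA, ISC): 7-cycle Morlet wavelets on a
  1 Hz grid spanning the band (8–13 Hz default; 8–12 Hz as a robustness
  switch), power averaged across frequencies. Samples within half a
  wavelet of either epoch edge (at the widest, 8 Hz wavelet: ±0.44 s) are
  flagged and excluded from window means. Envelopes are polyphase-
  resampled to 250 Hz before windowed analysis; on smooth envelopes this
  changes 5 s window means by well under 1% (tested).
* **Rolling windows**: half-open `[k, k+5)` s windows stepped by 1 s up to
  63 s — the shortest stimulus — giving 59 windows (61 for the 3 s
  robustness variant). A window grid never extends past the video.

## Neural statistics

* **FAA** = `ln P(F4) − ln P(F3)`; powers are floored at 1e−12 µV² before
  the log (a value with both powers floored is flagged unreliable).
  Positive FAA ⇔ relatively greater left-frontal activation (alpha power
  is inversely related to activity). Whole-video FAA uses Welch, windowed
  FAA uses window-averaged Morlet envelopes — two estimators on purpose,
  matching the two analysis granularities.
* **ISC** is computed on alpha-power envelopes, not band-passed voltage:
  envelopes are channel-averaged over Cz/C3/C4 per subject, then all
  n(n−1)/2 pairwise Pearson correlations within the window are averaged
  (unweighted). Per-channel-then-average is available as a sensitivity
  switch. Zero-variance series within a window exclude that subject's
  pairs (counted in the result). The per-channel ISC map computes
  whole-video single-channel ISC per video and correlates it across
  videos with the deal outcome and amount.

## Forecasting

One correlation per window across videos. Binary outcomes automatically
use the point-biserial coefficient, which is exactly Pearson on 0/1 coding
(asserted in tests); `method="rank"` gives Spearman. Windows with constant
metric or outcome are reported as NaN and flagged. P-values are
**unadjusted** across windows by default — mirroring exploratory
moment-to-moment reporting — with a Benjamini–Hochberg FDR variant
available and off by default. The package's own null simulations (zero
injected couplings; 50-seed sweep in the test suite) put the per-window
false-positive rate at the nominal 5% and additionally measure the
family-wise rate — the fraction of null studies with at least one
nominally significant window across the 59-window grid — which is many
times the nominal level because overlapping windows are strongly
dependent. This is exactly why the unadjusted masks must be read as
exploratory and why the FDR variant exists.

Bootstrap CIs resample **videos** with replacement (5,000 draws default,
percentile 2.5/97.5). The resampling unit was genuinely open — videos are
the forecasting unit (n = 14), subjects only enter through the group mean —
and video-level resampling is the default; degenerate resamples are
redrawn and counted.

## Regression models

Individual interest: `interest ~ predictors + (1|subject) + (1|video)`,
Gaussian, fitted via statsmodels MixedLM with two variance components.
Continuous predictors are z-scored within the estimation sample (binary
left 0/1), so coefficients are standardized. Fits are ML by default so
nested models are comparable by likelihood ratio (`χ² = 2ΔlogLik`,
df = parameter difference); REML is available for variance estimation.
AIC is `2k − 2logLik` with k counting fixed effects, both random-intercept
variances, and the residual variance. Funding amounts: video-level OLS
(n = videos) with standardized predictors, reporting β, SE, t, p, AIC and
adjusted R²; unfunded videos enter with amount 0 by default (a
`funded_only` switch drops them), since the inclusion rule was not
externally fixed.

## Power analysis

Each iteration draws `n_videos` bivariate-normal pairs with true
correlation ρ and applies the exact two-sided t-test of zero Pearson
correlation at α = 0.05; power is the rejection fraction over 5,000
iterations with a Wilson 95% binomial CI. At n = 14 this yields ≈ 6% for
ρ = 0.10 and ≈ 17–18% for ρ = 0.30, in line with the Fisher-z closed form
(tested to within 2 points for |ρ| ≤ 0.3). For ρ = 0.50 the simple
video-level mechanism gives ≈ 44–47%; a reported figure of ~38% for that
effect size would imply an additional unmodeled noise component (e.g.,
pair-level), so this module documents the simple design rather than
guessing at one.

## The synthetic study generator

`generate_study(SimConfig(...))` produces recordings, behavioral tables,
and the latent ground truth, deterministically per seed. Structure:

* Latent per-video interest `I_v` (standardized normal). Lab ratings:
  `μ + b·I_v + u_s + ε` mapped to five rounded/clipped 7-point items with
  per-item noise calibrated for Cronbach's α ≈ 0.9 (0.88 for the fourteen
  DC items). Population interest: mean of 497 simulated raters
  (slope 0.45, rater SD 1). Deal: logistic in `I_v` (γ₀ = 0, γ₁ = 1.5);
  if a draw leaves fewer than two videos in either class, the most
  extreme opposite-probability videos are flipped so funded/unfunded
  contrasts exist on every seed. Amounts:
  `scale·exp(0.5·I_v + 0.3·ξ)` for funded videos (scale $250k, putting the
  funded mean near $360k), 0 otherwise.
* EEG per subject: one volume-conducted 9–11 Hz alpha oscillator per
  subject (channels share frequency and phase and differ in amplitude
  envelope — this keeps neighboring electrodes realistically correlated),
  1/f pink background noise (12 µV RMS, 75% of its variance shared across
  scalp channels), per-channel slow amplitude drift (SD 0.15, < 1 Hz),
  and Poisson blinks (12/min, 120 µV raised-cosine on EOG with gain 0.45
  on Fp1/Fp2).
* **FAA injection**: F3 and F4 alpha amplitudes scaled by `(1 ∓ A_v(t)/2)`
  with `A_v(t) = a1·I_v·(early_boost for t < 10 s else 1)`, clipped to
  |A| ≤ 1.8 so amplitudes stay positive for extreme interest draws.
  Defaults a1 = 0.35, boost = 2 are the "strong" preset: the asymmetry is
  deterministic given the video, so group FAA recovers `I_v` with high
  fidelity — cleaner than real data (see Limitations).
* **ISC injection**: a smoothed (< 1 Hz) positive stimulus-locked envelope
  `s_v(t)` (mean 0.5, SD 0.25) shared by all subjects modulates the
  mid-central alpha amplitude with coupling
  `κ_v(t) = κ0 + κ1·D_v·t/duration` (κ0 = 0.25, κ1 = 0.9): funded videos'
  coupling ramps up over the pitch, producing the late funded/unfunded ISC
  divergence by construction.
* Generation at 256 Hz (power of two, > 5× the upper band edge);
  envelopes are downsampled to 250 Hz downstream. Durations default to
  uniform 63–112 s; `SimConfig.small()` (8 subjects × 8 videos × 63 s)
  is the reduced scale used for multi-seed validation runs, chosen so a
  50-seed sweep of the full pipeline stays at desk scale. One subject can
  optionally be truncated to 10 videos to exercise the missing-data path.

`simulate_rating_table` additionally provides the direct tabular
counterpart of the mixed model (known slope, crossed random intercepts)
for parameter-recovery and LRT-calibration checks without the EEG stack.

## What passing tests do and do not show

The generator reproduces the *structure* of the target data — alpha-band
dynamics, envelope coupling, rating reliability, outcome linkage — under
favorable signal-to-noise: the injected asymmetry has no subject-level
response heterogeneity, the shared envelope is exactly common across
subjects, and artifacts are limited to linear blink leakage. Recovery
results therefore validate the computational chain (that each stage
estimates what it claims, with calibrated nulls), not field-strength
effect sizes; real-data correlations will be attenuated by everything the
generator idealizes (nonstationary noise, muscle artifacts, individual
alpha topography, rater non-normality). Null-preset sweeps (both couplings
zero) confirm the per-window test size, and effect-size monotonicity is
checked across seeds.

## Numerical choices

* Power floor 1e−12 µV² before logs; Pearson r clipped away from ±1
  before Fisher transforms; degenerate bootstrap resamples redrawn.
* Sub-sample slack (one sample) is tolerated when the nominal −0.2 s
  baseline rounds to 51 samples at 256 Hz.
* Window means use only edge-valid envelope samples; a window with no
  valid samples is an error, not a NaN.
* All randomness flows from `numpy` `SeedSequence` spawning, so studies
  are byte-identical per seed and independent across purposes (videos,
  tables, subjects, blinks).
* MixedLM uses L-BFGS with a conjugate-gradient fallback; boundary
  variance estimates (a variance component at 0) are reported as-is.

## Known limitations

* EDF support is read-only; the JSON + float32 internal container is the
  round-trip format.
* The EOG cleanup removes only components linearly correlated with the
  recorded EOG; ICA-separable non-ocular artifacts are out of scope.
* The deal-flip safeguard slightly distorts the logistic outcome model on
  seeds where the draw was one-sided; it affects only the guarantee that
  funded/unfunded contrasts exist.
* Interpolation requires ≥ 2 good neighbors; epochs with heavily
  clustered bad channels fail loudly rather than being silently filled.
* The per-channel ISC map uses whole-video envelopes only; windowed
  channel maps would require substantially more computation.
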