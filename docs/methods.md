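# Methods

`eegage` estimates chronological age from resting multichannel EEG and
derives the brain-age gap (BrainAGE = predicted age − chronological age).
This note documents the models, conventions and numerical choices; the
README shows usage.

## Preprocessing

Recordings (EDF or BrainVision, read through `mne` and normalized to
microvolts) pass through:

1. **Band-pass 1–70 Hz**, Butterworth applied forward–backward
   (zero-phase). We use order 8: with a forward–backward pass the
   amplitude response is |H|², and an order-8 design is the lowest even
   order that leaves under 10% residual amplitude at 80 Hz while keeping
   the mid-band flat. Zero-phase filtering preserves cross-channel timing,
   which the lagged-envelope connectivity features depend on.
2. **Polyphase resampling** to 250 Hz (4 ms resolution), rational
   resampling via `scipy.signal.resample_poly`.
3. **Band-stop notches**, order-2 Butterworth, 1 Hz wide, zero-phase, at
   19.5 Hz and its harmonics below Nyquist, 60 Hz (AC line) and 26 Hz
   (vibration artifact) — the interference profile of EEG recorded inside
   an MR scanner. Notches at or above Nyquist are skipped with a warning.
   Gradient/cardioballistic artifact correction is out of scope; the
   pipeline assumes ordinary or already-corrected EEG.

A 1-Hz-wide IIR notch has a multi-second impulse response, so the first
and last few seconds of a filtered record are transient-contaminated;
tests of filter identities therefore measure steady state (≥5 s from the
edges). Non-finite samples are an ingestion error, never imputed.

**Montage.** Channel *i* of the bipolar montage is anode − cathode. The
shipped default is a longitudinal chain over a standard 32-electrode
10–20 cap — two lateral chains (8 pairs each), two parasagittal chains
(6 each) and a midline chain (3) — exactly 31 derived channels.
Hemisphere pairing maps each left-chain channel to its mirror-image
right-chain channel (14 pairs; midline excluded). Filtering precedes
montage derivation; both are linear so the order is immaterial.

**Epochs.** 60-s epochs with 50% overlap;
`m = floor((duration − len)/(len·(1 − overlap))) + 1`, trailing partial
data discarded (padding would bias epoch-averaged features). An 8-min
record gives m = 15; the 120-s short mode used in tests gives m = 3.

## Features (2407 per subject)

Bands: δ 0.5–4, θ 4–7, α 7–13, β 13–30 Hz; W = 0.5–30 Hz is the
whole-range reference. A band owns bins with lo ≤ f < hi, so the four
bands tile W exactly and relative powers sum to 1. Per-epoch features are
averaged over the m epochs. Per band and channel:

- **Amplitude (6)**: total power (mean x²), sample SD, skewness
  (m₃/m₂^1.5), raw kurtosis (m₄/m₂², Gaussian → 3), mean and SD of the
  envelope. The envelope is the *squared* magnitude of the analytic
  signal, |x + jH{x}|². The raw mean is omitted: a band-passed signal is
  zero-mean by construction.
- **rEEG (7)**: peak-to-peak voltage of 2-s windows (50% overlap):
  mean, median, 5th/95th percentiles, SD, coefficient of variation
  (SD/mean), and quantile skewness ((p95 − med) − (med − p5))/(p95 − p5).
- **Spectral (6)**, from the epoch's Welch PSD (2-s Hamming windows, 50%
  overlap, per-segment constant detrend, one-sided density scaling)
  restricted to the band: absolute and relative power, Wiener entropy
  (spectral flatness = geometric/arithmetic mean of in-band PSD),
  normalized Shannon entropy of the in-band distribution, 95% spectral
  edge frequency, and the mean squared difference between consecutive
  short-time amplitude spectra.
- **Connectivity (5 per band, pair-aggregated)**: brain symmetry index
  BSI = mean over in-band bins of |(P_L − P_R)/(P_L + P_R)| with P_L, P_R
  the hemisphere-mean channel PSDs (0 = symmetric, 1 = one-sided);
  median across pairs of the maximum lagged Spearman correlation between
  band-specific envelopes and of its argmax lag (±200 ms; positive lag =
  right hemisphere leads); mean in-band magnitude-squared coherence and
  the median across pairs of the frequency of maximum coherence.
- **Fractal dimension (1 per channel, unfiltered)**: Higuchi FD with
  kmax = 6, OLS slope of log L(k) vs log(1/k), clipped to [1, 2]
  (line → 1, white noise → 2).

**Lagged Spearman convention.** Each whole-epoch envelope is ranked once
and the rank series are Pearson-correlated at each integer-sample lag
(exact windowed sums via cumulative sums and one FFT cross-correlation).
Re-ranking each lag window would cost O(lags · n log n) per pair for a
negligible numerical difference; the rank-once definition is the one the
naive oracle implements too.

Feature names are `domain.feature.band.channel`; FD uses the band token
`broadband`, connectivity the channel token `pairs`.

## Feature reduction

Response-blind, fit once on the full table (it never sees age):
(1) near-zero-variance removal — constant columns, plus columns whose
most-common/second-most-common frequency ratio exceeds 95/5 with under
10% unique values; (2) iterative correlation filtering — repeatedly take
the remaining pair with the highest |Pearson r| and, while it reaches
0.9, drop the member with the larger mean absolute correlation against
all remaining columns (ties break to the earlier column). The output is
guaranteed to contain no pair with |r| ≥ 0.9. On short-mode synthetic
cohorts roughly half of the 2407 columns survive.

## Modeling

Nested cross-validation: outer K_O = 10 folds estimate generalization;
defaults for tuning are K_I = 10 inner folds × R = 5 repeats. Base
regressors: elastic net, RBF-kernel SVR, random forest, gradient-boosted
trees (XGBoost), and Gaussian-process regression with a polynomial kernel
(DotProduct^degree, fixed hyperparameters, an extra 1/√p feature scaling
keeps the Gram matrix O(1) at degree 3). Penalized/kernel methods see
z-scored features (statistics from the outer-training split only); tree
methods see raw features. Grids ship ordered most-parsimonious first; the
one-SE rule picks the first grid point whose mean inner RMSE is within
one standard error (sd/√resamples) of the minimum.

**Stacking.** Per outer fold, each method's held-out inner predictions
(pooled over the K_I × R resamples at the selected hyperparameters) form
the training matrix of a general linear model (intercept + one
coefficient per method). The GLM is fit under K_Ens = 10-fold CV: because
base predictions are strongly collinear, the CV selects the solve's
shrinkage from a small ladder (plain OLS plus light ridge levels,
penalties relative to the Gram diagonal, intercept unpenalized) and the
selected solve is refit on all rows. An exactly singular system falls
back to a tiny ridge. The fold's held-out subjects are predicted by the
weighted combination of the refitted base models; concatenating folds
yields exactly one unbiased prediction per subject.

Metrics: R² = 1 − SS_resid/SS_total, MAE, RMSE, Pearson r — pooled and
per-fold (mean ± sd). BrainAGE is predicted − chronological age from
outer-fold predictions only; on noisy cohorts it shows the expected
negative slope against age (regression to the mean). Sex-stratified
metrics are a reporting option, never a modeling input. One master seed
drives folds, per-method fits and subsampling through deterministic child
seeds; identical config + seed reproduces results bit-for-bit
(single-threaded tree learners).

## Interpretation

Per fold, each base model yields a nonnegative importance vector —
|coefficients| (elastic net), impurity importances (forest/boosting), or
seeded permutation importance (SVR/GP) — normalized to sum 1 (raw scales
are incomparable), combined with the normalized absolute stack weights,
and rescaled to sum exactly 100 per fold; the report averages folds and
annotates each feature's marginal Pearson r with age. Partial-dependence
curves sweep one feature over 25 quantile-spaced grid points of the
fold's training range; consistency across folds is the mean pairwise
Pearson correlation on a common grid. Spatial summaries parse feature
names into channel × band grids per domain plus domain- and band-level
percentage shares (each summing to 100). Plotting is deliberately not a
dependency; grids are plain tables any topomap tool can consume.

## Synthetic cohorts

Each subject is a sum of band-limited oscillators (narrowband-filtered
Gaussian noise, randomized per channel) plus 1/f^γ background noise
(γ = 1), on the 32-electrode cap. Defaults, chosen once to mirror the
adult maturation effects the EEG-aging literature reports: alpha RMS
amplitude 12 µV at age 38 declining 0.15 µV/yr; alpha peak 10.2 Hz
declining 0.025 Hz/yr (per-subject jitter sd 0.3 Hz); delta declining
0.04 µV/yr; theta/beta rising mildly; per-subject lognormal amplitude
jitter σ = 0.2 (so age explains far from all variance); right-hemisphere
amplitudes +10% (drives BSI); half of each oscillator's amplitude is
shared across channels (drives coherence/envelope correlation); in-band
SNR 2. Ages are uniform on 18–58. The sex label is balanced and carries
no generative effect by default. `age_effects` can restrict the planted
signal to the alpha amplitude (recovery tests) or remove it entirely (the
leakage canary: a correctly hygienic pipeline scores R² ≈ 0 there).

What the generator does *not* emulate: non-stationarity, ocular/muscle
artifacts, volume-conduction topography, nonlinear age trajectories and
inter-channel covariance structure of real EEG. Passing recovery tests
therefore demonstrates the pipeline's correctness and hygiene, not
real-data effect sizes; headline numbers on synthetic cohorts depend on
the planted effect and are not comparable to performance on clinical
recordings.

## Problem sizes and desk-scale settings

Tests and the acceptance script run short-mode cohorts (120-s or 60-s
recordings, n ≤ 200) with `NCVConfig.fast()`: K_O = 5, K_I = 5, R = 1,
one-to-two-point grids, 100 trees. These are the package's desk-scale
defaults for synthetic validation; the full protocol (K_O = K_I = 10,
R = 5, full grids) remains the `NCVConfig` default for real studies.
Null-hygiene runs additionally use single-point grids and K_I = 3, since
the leakage property does not depend on tuning quality.

## Known limitations

- The correlation filter is O(p²) memory and iterative; beyond ~10⁴
  features a blocked implementation would be needed.
- Welch/rEEG windows assume epochs are at least one window long (2 s).
- The EDF writer quantizes to 16 bits over each channel's observed range.
- GP and SVR importance uses permutation with a single repeat by default;
  increase `n_repeats` for publication-grade rankings.
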