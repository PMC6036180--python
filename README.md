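# eegage

Chronological-age prediction and **BrainAGE** (brain-age gap) estimation
from resting multichannel EEG.

Aging changes the resting EEG in well-replicated ways — alpha power and
peak frequency decline, band power shifts toward higher frequencies,
signal complexity changes. `eegage` turns those changes into a
quantitative brain-age estimate: it extracts a large, *interpretable* set
of per-channel, per-band signal features, removes redundant ones,
predicts age with a rigorously nested-cross-validated stacked ensemble,
and reports which features drove the prediction. The per-subject residual

    BrainAGE_s = predicted_age_s − chronological_age_s

is the quantity of interest for studying accelerated or delayed brain
aging. The package is for researchers with resting EEG plus ages who
want an age model whose predictors they can read.

## Pipeline

1. **Preprocess** (`eegage.preprocess`): band-pass 1–70 Hz (zero-phase
   Butterworth), resample to 250 Hz, notch known interference (19.5 Hz
   harmonics, 60 Hz, 26 Hz), derive a 31-channel bipolar montage from a
   32-electrode 10–20 cap, segment 60-s epochs with 50% overlap.
   EDF and BrainVision are read via `mne`.
2. **Extract features** (`eegage.features`): per channel × band
   (δ 0.5–4, θ 4–7, α 7–13, β 13–30 Hz), epoch-averaged —
   6 amplitude × 4 × 31, 7 range-EEG × 4 × 31, 6 spectral × 4 × 31,
   5 connectivity × 4 (brain symmetry index, lagged envelope
   correlations, coherence), 31 Higuchi fractal dimensions:
   **2407 named features** (`domain.feature.band.channel`).
3. **Reduce** (`eegage.reduction`): drop near-zero-variance columns, then
   iteratively drop one member of every pair with |Pearson r| ≥ 0.9
   (response-blind).
4. **Model** (`eegage.modeling`): nested CV (outer 10-fold; inner
   10-fold × 5 repeats) tuning elastic net, RBF-SVR, random forest,
   gradient-boosted trees and polynomial-kernel Gaussian-process
   regression by grid search with the one-standard-error rule; a GLM
   stack learns weights on the inner held-out predictions and combines
   the base models; pooled and per-fold R²/MAE/RMSE/r plus BrainAGE.
5. **Interpret** (`eegage.interpretation`): per-fold importance
   normalized to sum 100, fold-averaged, with each feature's correlation
   with age; partial-dependence curves per fold with a consistency score;
   channel × band importance grids and domain/band shares.

`eegage.simulate` generates age-structured synthetic EEG cohorts (alpha
amplitude/peak frequency declining with age, 1/f background, hemispheric
asymmetry) with full ground truth, so the whole pipeline is testable
without any data download. See `docs/methods.md` for the model details
and `examples/` for narrative scripts.

## Worked example

`python examples/03_reduce_and_model.py` builds a 40-subject synthetic
cohort end-to-end and prints:

```
cohort: 40 subjects x 2407 features
after reduction: 1090 features (1317 dropped at |r| >= 0.9 or near-zero variance)

stacked ensemble, pooled over outer folds (n=40):
  R^2  = 0.345
  MAE  = 7.85 years
  RMSE = 9.27 years
  r    = 0.588

per-method pooled R^2 (before stacking):
  enet  0.360
  svr   0.167
  rf    0.336
  xgb   0.267
  gp    0.365

first subjects' BrainAGE (predicted - chronological age, years):
              age  predicted_age  brainage
subject_id
sub-000     23.14          25.91      2.76
sub-001     37.97          40.25      2.28
sub-002     42.06          27.77    -14.29
sub-003     19.15          33.79     14.64
sub-004     23.92          34.10     10.19
```

Reading the numbers: the planted alpha–age effect is recovered even at
n = 40 (pooled R² ≈ 0.35, r ≈ 0.59 between predicted and true age; at
n = 200 the same pipeline reaches R² ≈ 0.5), the stack sits at the level
of the best base models, and BrainAGE is positive for subjects the model
judges EEG-older than their years — with the expected
regression-to-the-mean pattern (young subjects pulled up, old pulled
down). `examples/04_interpret_importance.py` then shows that alpha-band
features top the importance ranking when the age signal is planted only
in the alpha amplitude.

A thin CLI mirrors the stages:

```bash
eegage simulate --n 20 --duration 120 --out cohort/
eegage extract --in cohort/ --out features.csv
eegage reduce --in features.csv --out reduced.csv
eegage train --in reduced.csv --fast --out results/
eegage interpret --features reduced.csv --fast --out interp/
```

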