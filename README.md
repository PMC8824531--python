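# cogdecode

Single-trial cognitive-state decoding from epoched EEG/MEG recordings.

The package implements a complete decoding pipeline on labeled voltage
epochs (trials × channels × samples):

1. **Time-frequency substrate** — complex Morlet wavelet power (78 linearly
   spaced frequencies, 3–80 Hz, 5 cycles), decimated to 50.25 Hz, summed
   into theta/alpha/beta/gamma bands and z-scored per band
   (`cogdecode.signal_model`).
2. **Eight feature families** over (band × 400-ms window × channel/region)
   cells: mean, variance, Shannon entropy, mean resultant phase length,
   region-pair Pearson correlation, region-pair phase-locking value, AR(4)
   coefficients, and CSP-filtered variances — 6768 columns in the default
   32-channel configuration (`cogdecode.features`).
3. **Feature selection** — Fisher-score filter, sequential forward
   selection with a cross-validated balanced-accuracy criterion, and the
   filter→wrapper combination (top 100 by Fisher score, best 10 by SFS)
   (`cogdecode.selection`).
4. **Class balancing** — SMOTE oversampling of minority classes to the
   majority count (`cogdecode.balancing`).
5. **Classifiers** — full-covariance Gaussian discriminant ("naive
   Bayes"), logistic regression, LASSO regression on ±1 class codes, and
   a linear soft-margin SVM, all behind one train/score/predict contract
   (`cogdecode.classifiers`).
6. **Multiclass schemes** — one-vs-rest score voting and an
   optimal-partition binary decision tree (`cogdecode.multiclass`).
7. **Evaluation** — stratified cross-validation with strict
   training-fold-only fitting of every transform, balanced accuracy,
   label-permutation chance levels, and per-stage runtime accounting
   (`cogdecode.evaluation`).
8. **Synthetic data** — a generator of 1/f-background epochs with planted
   band/window/channel effects and a Monte-Carlo Bayes-accuracy oracle,
   so the whole pipeline is testable without external recordings
   (`cogdecode.synthetic`).

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (feature-space
dimensionality, window arithmetic, oracle equivalences, synthetic-data
calibration, and qualitative method orderings); the rest of the suite is
unit and property tests per module.

## CLI

Every stage is scriptable through one YAML config (see
`cogdecode.config.PipelineConfig` for the keys):

```sh
cogdecode generate --config config.yaml --out epochs.npz   # synthetic data
cogdecode extract  --config config.yaml --out features.tsv # feature matrix
cogdecode run      --config config.yaml --out report.json  # cross-validated evaluation
cogdecode chance   --config config.yaml --out chance.json  # permutation null
cogdecode inspect  report.json                             # pretty-print
```

A minimal config:

```yaml
synthetic:
  n_trials: {0: 40, 1: 40}
  seed: 0
  effects:
    - {type: AmplitudeEffect, label: 1, osc_index: 0,
       channels: [P3, P4], window_ms: [400.0, 800.0], factor: 2.0}
families: [mean, variance, entropy, phase, correlation, phase_sync, ar, csp]
selection: filter+wrapper
classifier: naive_bayes
cv_folds: 5
min_trials: 20
seed: 0
```

Exit codes: 0 success, 1 input validation failure, 2 runtime error.

Epoch input formats: the native NPZ/HDF5 exchange layout
(`{data, labels, fs, channel_names, t0_ms}`), EEGLAB `.set` epoch files,
and (with the `readers` extra) FIF/EDF.

## Notes

- Fold discipline: band-power normalization statistics, CSP filters,
  feature selection, and SMOTE are all fitted inside the training fold
  only; pooling normalization over all trials is available
  (`normalization_pool: all`) but must be explicitly allowed and is
  flagged in the report.
- Determinism: every stochastic step descends from the single config
  seed; running the same config twice yields an identical report
  (timing fields aside).
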