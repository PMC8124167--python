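# tremorkit

Smartwatch accelerometers are attractive instruments for movement-disorder
assessment: they are cheap, worn on both wrists, and sensitive enough to
capture tremor amplitudes below what the eye can see (<0.01 g). Before
their readings can support a diagnosis, two questions must be answered:
**how accurately does a consumer watch measure oscillation frequency and
amplitude** against a gold-standard reference on a shaker table, and **how
much diagnostic signal do engineered features of a standardized wrist
examination carry** for separating Parkinson's disease (PD) from similar
movement disorders (DD) and healthy controls?

tremorkit implements both analyses end to end, driven by a synthetic-data
module that emulates the shaker-table experiment and a labeled
450-participant two-wrist examination cohort, so every stage is testable
and reproducible offline:

* **`tremorkit.simulate`** — watch imperfection models (sample-rate
  deficit, timestamp jitter, white self-noise, zero-g offset, amplitude
  gain error), shaker campaigns with an ideal velocity reference, and
  labeled PD/DD/healthy cohorts performing the 11-step examination on both
  wrists with class-conditional tremor phenotypes and questionnaires.
* **`tremorkit.metrology`** — the validation chain: reference velocity →
  acceleration in g; timestamp-derived sample rate `(n−1)/(tₙ−t₁)`;
  dominant frequency via a mean-removed FFT zero-padded to an exact
  0.01 Hz bin grid; oscillation amplitude as the mean of 20 consecutive
  half peak-to-peak ranges; self-noise RMS, zero-g offset and Welch PSD.
  For a tone of frequency *f* sampled at rate *r_a* but analysed assuming
  *r_n*, the dominant frequency comes out at *f·r_n/r_a* — correcting the
  spectral axis with the timestamp-derived rate removes the growing
  frequency error of the nominal-rate analysis.
* **`tremorkit.features`** — 303 features per participant: per step and
  wrist the norm-series percentiles (30–70 % in 5 % steps), sample SD and
  three spectrum-shape polynomial coefficients; per step the left/right
  90th-percentile dominance ratio; plus six questionnaire features.
* **`tremorkit.classification`** — statsmodels-style model/results
  objects for nested cross-validation (5 outer × 5 inner stratified folds;
  undersample → standardize → PCA → percentile selection → RBF-SVM /
  boosted trees / MLP; hyperparameters chosen by inner balanced accuracy)
  and bootstrap split-gain feature importance.
* **`tremorkit.cli`** — `tremorkit simulate|validate|features|classify|run-all`.

## Worked example

```python
from tremorkit import RunConfig, run_validation_study
from tremorkit import generate_cohort, build_feature_table, nested_cv

# 1) sensor validation on the default 43-measurement shaker campaign
report = run_validation_study(RunConfig(seed=1))
print(report.summary)

# 2) disease classification on a synthetic examination cohort
cohort = generate_cohort(40, 25, 20, seed=1)   # PD / DD / healthy
X, y = build_feature_table(cohort)
print(nested_cv(X, y, "pd_vs_dd", seed=1).summary())
```

The validation summary prints:

```
{'n_measurements': 43, 'n_deviation_rows': 42,
 'max_abs_freq_dev_nominal_hz': 0.090, 'max_abs_freq_dev_corrected_hz': 0.0,
 'max_abs_amp_dev_g': 0.0040, 'max_abs_amp_dev_le_0.04g_g': 0.00019,
 'max_noise_rms_g': 0.00070, 'max_abs_zero_g_offset_g': 0.00017,
 'max_rate_shortfall_hz': 0.600}
```

Read: watches run up to 0.6 Hz below their 100 Hz specification, which
alone produces dominant-frequency errors up to 0.09 Hz at 15 Hz when the
nominal rate is assumed; after correcting the spectral axis with the
timestamp-derived rate the frequency deviations vanish to below one
0.01 Hz bin. Amplitude deviations stay below 0.002 g up to 0.04 g drive
amplitude and below 0.005 g overall (the watches over-read large
amplitudes), and the self-noise stays below 0.001 g RMS with a zero-g
offset below 2×10⁻⁴ g — all well under clinical relevance thresholds.

The classification summary prints:

```
Nested cross-validation: task=pd_vs_dd estimator=svm_rbf seed=1
n=65 samples, 303 features, 5 outer folds

metric                mean      sd
accuracy             0.954   0.042
balanced_accuracy    0.948   0.050
precision            0.956   0.061
recall               0.975   0.056
f1                   0.963   0.034
```

Mean and SD are over the five outer test folds; precision/recall/F1 refer
to the PD-positive class and balanced accuracy has a 0.5 chance level.
Synthetic cohorts separate more cleanly than real clinical data — the
generator is a correctness testbed, not a performance forecast (see
`docs/methods.md`).

## Command-line interface

```bash
tremorkit simulate shaker --seed 1 --out campaign/
tremorkit validate --campaign campaign/ --out report.csv --plots
tremorkit simulate cohort --config study.yaml --out cohort/
tremorkit features --cohort cohort/ --out features.csv
tremorkit classify --features features.csv --task pd_vs_dd --estimator mlp \
    --seed 1 --out result.json
tremorkit run-all --seed 1 --out study/
```

All randomness flows from `--seed`; a persisted config plus seed
reproduces a run byte-identically, and every artifact embeds the config
hash, seed and package version.
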