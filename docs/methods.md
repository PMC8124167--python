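# Methods

This note documents the models, estimators and numerical choices behind
tremorkit: what is simulated, how the metrology chain measures it, how the
classification pipeline is cross-validated, and what the synthetic data do
and do not establish about real recordings.

## Sensor imperfection model

A watch accelerometer is described by six parameters (`SensorModel`):

| parameter | unit | series-3 default | series-4 default | why |
|---|---|---|---|---|
| `nominal_rate` | Hz | 100 | 100 | the officially specified rate an analyst would assume |
| `actual_rate` | Hz | 99.6 | 99.4 | consumer watches run up to 0.6 Hz short of specification |
| `timestamp_jitter_sd` | s | 5×10⁻⁴ | 5×10⁻⁴ | clock read-out scatter, well below the 10 ms interval |
| `noise_rms` | g | 5×10⁻⁴ | 7×10⁻⁴ | white self-noise per axis; the newer build is slightly noisier |
| `zero_g_offset` | g | 1×10⁻⁴ | 1.5×10⁻⁴ | constant bias on every axis |
| `gain_error` (> onset 0.05 g) | — | 1.03 | 1.04 | watches over-read large amplitudes; onset at 0.05 g |

The ADC is modelled as sampling uniformly at `actual_rate`; the jitter is
applied to the *recorded* interior timestamps only, with the first and last
stamps anchoring the record. This keeps the timestamp-derived mean rate
`(n−1)/(t_n−t_1)` equal to the true rate, which is what the rate-correction
analysis exploits; it deliberately does not model drifting clocks.

The reference instrument is ideal: it records the exact analytic velocity
of the driven sinusoid, scaled by a constant counts-per-(mm/s) gain. Its
frequency-dependent response is out of scope (real seismometer self-noise
is orders of magnitude below the watches').

## Shaker campaign

The default protocol has 43 entries: a 3–15 Hz sweep in 1 Hz steps at
0.01 g, a 14-point amplitude sweep at 5 Hz over 0.002–0.1 g, repeats at 7
and 10 Hz with varied amplitude, and one zero-vibration test. Each
measurement lasts 20 s. The individual settings of a real campaign are not
uniquely determined by its published envelope, so this protocol is a
representative stand-in that covers the same frequency/amplitude box with
the same measurement count.

## Metrology chain

**Reference conversion.** counts ÷ gain → mm/s; differentiate → mm/s²;
÷1000 ÷ 9.81 → g. Differentiation uses a 41-tap equiripple FIR
differentiator (passband 0–0.45·fs), flat to <0.1 % over 3–15 Hz, with
mirror padding; edge effects are confined to the outer 20 samples. Plain
central differences were rejected because their response `sin(ωΔt)/Δt`
loses 14 % at 15 Hz with 100 Hz sampling, which would dominate every
amplitude comparison.

**Sample rate.** `(n−1)/(t_last−t_first)` from the device timestamps.

**Dominant frequency.** Mean removal, zero-padding at the end to
`ceil(rate/bin_spacing − 10⁻⁹)` samples (10 000 at 100 Hz → exactly
0.01 Hz bins; the epsilon keeps 1-ulp rate noise from inflating the pad
target), magnitude argmax over (0, rate/2], lowest frequency on exact
ties. No resampling of jittered data: the rate correction changes only the
assumed rate, both in the frequency axis and the pad target. For a
noiseless tone of frequency f sampled at rate r_a but analysed at r_n the
estimator returns f·r_n/r_a within one bin — this closed form is what makes
the uncorrected deviations grow with frequency and vanish after
correction.

**Oscillation amplitude.** Mean removal; polyphase upsampling ×8 so that
sub-sample extrema are resolved (at 15 Hz / 100 Hz the raw per-sample peak
error averages ≈3.6 %, upsampled ≈0.06 %); a zero-phase 4th-order
Butterworth low-pass at 3× the dominant frequency suppresses wide-band
sensor noise before extrema picking; rising zero-crossings (minimum
separation 0.6 periods) segment the series; the first 20 full periods
after a 0.5 s settling margin each contribute a peak-to-peak range; the
estimate is mean/2 with SD/2 over the 20 periods (the SD is over periods,
not repeated measurements). The settling margin also keeps differentiator
and filter edge transients out of the analysed periods. Residual positive
bias from noise maxima is what makes watches read slightly high, matching
the simulated envelopes (≤0.002 g below 0.04 g; ≤0.005 g overall with the
gain error active above 0.05 g).

**Self-noise.** Zero-g offset is the signal mean; RMS is mean-removed;
the PSD is a one-sided Welch estimate (Hann, 50 % overlap, segments ≤1024
samples) normalized as a density so its integral matches the variance.

## Examination cohort model

Each participant performs 11 steps (two rest-tremor steps of 20 s, seven
action/posture steps of 10 s, a 1 kg-weight step and a 20 s entrainment
step) on both wrists. A recording is

    a(t) = ĝ + u · A(t)·sin(2πf t + φ) + noise + offset,

with ĝ a constant 1 g gravity direction per wrist, u a tremor direction
with |u·ĝ| ≥ 0.3 (wrist tremor is never orthogonal to gravity; this keeps
the tremor fundamental in the Euclidean-norm series rather than the
rectified double frequency), and A(t) a ±30 % slow modulation (0.1–0.4 Hz).

Class-conditional phenotypes (per-participant draws):

* **PD** — rest tremor 4–6 Hz; amplitude log-normal (median 0.02 g,
  σ=0.6); amplified ×1.5 under cognitive distraction (step 1b); attenuated
  ×0.3 during action; left/right asymmetry ×2–4; 30 % akinetic-rigid
  subtype with subtle tremor (median 0.003 g) throughout.
* **DD** (essential-tremor-like differential diagnoses) — action tremor
  4.5–8 Hz prominent in the posture/kinetic steps, rest amplitude ×0.2
  (40 % have a dystonic-like rest component ×0.7); mild asymmetry; 30 %
  entrain to the stomp pace (1.5–2.5 Hz) in step 10.
* **Healthy** — physiological 8–12 Hz, amplitude ≤0.005 g everywhere.

All step factors (except healthy) carry per-step log-normal jitter
(σ=0.4): no two patients express the protocol identically, and the
PD-vs-DD contrast is deliberately harder than either disease-vs-healthy
contrast, as in clinical practice. Questionnaire model: ages truncated
normal per class (PD 66.26±9.61, DD 60.82±12.87, healthy 61.45±10.63,
bounds 30–90); non-motor "yes" probability 0.40/0.25/0.10 per item (30
independent items); alcohol effect on tremor 0.10/0.50/0.05; family
history 0.20/0.10/0.10. Height and weight are class-independent.

**What the generator does not emulate:** voluntary-movement artifacts in
the action steps, tremor harmonics and re-emergent rest tremor latency,
bradykinesia kinematics, drifting wrist orientation, and any coupling
between questionnaire answers and motor severity. Passing tests therefore
establish that the pipeline measures what the generator encodes — not that
real cohorts separate at the accuracies seen here; on real data the
absolute accuracies would be substantially lower even though the pipeline
mechanics (fold hygiene, metric definitions, rate correction) carry over
unchanged.

## Feature table

303 features per participant: per step and wrist, nine percentiles
(30–70 % in 5 % steps, linear interpolation) of the raw norm series, the
sample SD (n−1), and three polynomial coefficients (degree-3 fit in
frequency of the unit-maximum amplitude spectrum of the mean-removed norm
over 0.5–20 Hz; the constant term is dropped so exactly three coefficients
remain); per step, the left/right ratio of the 90th percentiles of the
mean-removed norms (floor 10⁻⁶ g on a degenerate denominator); plus age,
height, weight, family history, alcohol effect and the non-motor yes-count.
Medication is deliberately not a feature. Missing recordings yield missing
features imputed with the cohort median (skipped with a warning for a
cohort of one). The spectrum fit uses the norm series, not per-axis
spectra (which would yield nine coefficients and break the fixed schema);
a per-axis variant exists behind `fft_poly_features(per_axis=True)`.

## Classification

Five stratified outer folds estimate test performance; five stratified
inner folds grid-search hyperparameters by balanced accuracy. Before every
inner fit and before each outer refit the majority class is undersampled
without replacement to the minority size; the draw is made once per fold
(a seeded sampler re-draws identically for identical fold data, so it is
shared across the grid, which also enables caching of the fitted
transforms). The pipeline per fit: standardize → PCA (retained variance
0.80/0.90/0.95) → top-percentile univariate selection (mutual information
by default, ANOVA-F optional; deterministic top-k, lower index wins ties;
25/50/75/100 %) → estimator. Grids: RBF-SVM C ∈ {0.1, 1, 10}, γ ∈ {1/d,
0.01, 0.001}; boosted trees (LightGBM) depth {4, 6}, 200/500 iterations,
learning rate {0.03, 0.1}; MLP with two hidden layers {(64,32), (128,64)},
L2 {10⁻⁴, 10⁻²}, 400 iterations. All transforms are fitted on training
rows only; the results object records per-fold train/test indices, the
undersampled rows and the fitted scaler means so leakage is auditable
after the fact. Reported per outer fold: accuracy, balanced accuracy
(mean of per-class recalls; 0.5 chance level), precision, recall and F1
of the positive class (PD, or PD+DD for the pooled task).

Bootstrap feature importance (disease-vs-healthy by default): rows are
resampled with replacement, balanced by undersampling, a LightGBM
classifier (150 trees, depth 4) is fitted, and its total split gain per
feature — normalized to sum to one — is recorded per resample, then
aggregated over the six feature groups.

## Problem sizes and determinism

The packaged studies run at the scale of the emulated study itself: a
43-measurement campaign, 100 zero-vibration recordings per watch model,
and a 450-participant cohort (260 PD / 101 DD / 89 healthy); these sizes
keep every stage comfortably within a desk-scale single-CPU budget. Every
generator and estimator takes one integer seed; child streams are derived
via `SeedSequence` spawning, so identical seeds give byte-identical
campaigns, cohorts and cross-validation results, and each participant's
data depends only on the seed and their position.

## Known limitations

* The amplitude estimator assumes a narrowband oscillation; multi-tone or
  strongly non-sinusoidal tremor would need band-specific segmentation.
* The reference is noiseless and response-free; a pole-zero instrument
  deconvolution is out of scope.
* The nested CV treats participants as independent (one examination per
  participant); repeated measurements would require grouped folds.
* Synthetic accuracies exceed what heterogeneous clinical data yield; the
  cohort generator is a testbed for pipeline correctness, not a forecast
  of diagnostic performance.
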