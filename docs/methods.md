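# Methods and design notes

## Problem setting

The package targets binary classification of depressive disorder (DD)
patients versus healthy controls (HC) from resting-state, eyes-closed EEG
restricted to six frontal electrodes (Fp1, Fp2, F3, F4, F7, F8). Frontal
low-density montages matter practically because setup time scales with
electrode count; scientifically, frontal rhythms — beta power in
particular — are repeatedly reported as altered in DD. The unit of
classification is a 4 s epoch of band-filtered EEG; subject-level claims
must aggregate epoch predictions or use subject-level cross-validation
(below).

## Synthetic cohort model

Clinical EEG of this kind is rarely shareable, so the package generates
surrogate cohorts that preserve the statistical features the pipeline
depends on. Per channel:

```
x(t) = g_subj · ( b(t) + Σ_bands o_band(t) ) + a(t)
```

* `b(t)` — Gaussian noise spectrally shaped to `1/f^α` (default α = 1, the
  typical broadband EEG slope), scaled to 10 µV RMS. The realized log–log
  periodogram slope is within ±0.3 of −α over 2–40 Hz.
* `o_band(t)` — white noise passed through the band's 4th-order Butterworth
  filter. Its variance is calibrated against the background's band-integrated
  power so that the configured per-band "power ratio" equals the
  group-b/group-a ratio of **total** band power (background + oscillation):
  for group a the oscillation carries `osc_strength × P_bg` (default 1×);
  for group b it carries `ratio · (P_bg + v_a) − P_bg`. Ratios below
  `P_bg/(P_bg+v_a)` (0.5 at the default strength) are not realizable and are
  rejected.
* `g_subj` — lognormal per-subject gain (σ = 0.1), modelling inter-subject
  amplitude variation (skull thickness, impedance).
* `a(t)` — optional ocular artifacts: raised-cosine transients of 0.5–2 s,
  5–10× the background SD, with a fixed spatial pattern that is strongest on
  the frontopolar pair (gain 1.0) and decays posteriorly (F: 0.45, C: 0.15,
  else 0.1). The rank-one spatial structure makes them a separable source
  for ICA.

Group sizes default to 41 patients / 34 controls (the imbalance typical of a
modest clinical study) with 10 min recordings at 250 Hz, but every field is
configurable. A fixed `(spec, seed)` pair yields bit-identical cohorts.

What the generator does **not** model: HAMD severity, age/sex covariates,
inter-channel correlation of the background, non-stationarity, line noise,
muscle/ECG artifacts, or any depression electrophysiology beyond band-power
shifts. Passing results on synthetic cohorts therefore validate the
*machinery* (filters, ICA, folds, optimization, metrics) and the pipeline's
ability to recover a planted band-localized effect — not clinical accuracy.

## Preprocessing

Stage order is fixed: channel selection → downsample → baseline correction →
ICA → 4 s segmentation → bandpass (a `band_before_segment` flag exists,
default off). Choices where the protocol leaves room:

* **Downsampling** 250 → 125 Hz uses an anti-aliased decimator; non-integer
  ratios fall back to polyphase resampling.
* **Baseline correction** is whole-recording per-channel mean subtraction.
* **ICA**: FastICA with as many components as channels, fixed seed.
  A component is rejected when (a) its excess kurtosis is a robust outlier
  among the components (median/MAD z > 3) *and* exceeds an absolute floor of
  1.0 — with only six components a z-score against the component population
  alone would be meaningless, and genuine EEG components are near-Gaussian
  (|k| < 0.1) at these lengths while blink components reach k ≈ 5–10 — or
  (b) it correlates > 0.7 with a low-passed (< 4 Hz) frontopolar mean trace.
  Reconstruction from all components is numerically exact, so the
  `keep-all` policy is an identity and rejection is the only lossy step.
* **Bandpass**: Butterworth of prototype order 4 (the bandpass
  transformation doubles the polynomial order), applied zero-phase
  (forward–backward; magnitude response squared, no phase distortion) by
  default, with a single-pass mode available. Each 4 s epoch is
  reflection-padded by 1 s per side before filtering so the filter transient
  does not consume real data. Single-pass cutoff gain is −3 dB ± 0.5 at the
  band edges; zero-phase is −6 dB.

## Architectures

Both models consume `(batch, 6, 500)` float arrays (4 s at 125 Hz).

**MRCNN-RSE.** Two branches with kernels (4, 3, 3) and (10, 3, 3); each
convolution is followed by batch normalization and GELU; max pooling
(size 2) follows convolutions 1 and 3 (the placement is a design choice; the
protocol fixes "three convolutions, two poolings" per branch but not the
interleaving). Valid-mode convolution shrinks the two branches' time axes
unequally, so branch outputs are center-cropped to the shorter length before
channel-wise concatenation. One RSE block then recalibrates the concatenated
features (applying it per branch was the alternative): the gating path
squeezes the incoming feature map by global average pooling and maps it
through a reduction-8 ReLU bottleneck and a sigmoid expansion to per-channel
gates in (0, 1); the residual path applies two kernel-1 convolutions; output
is `input + gates ⊙ transformed`. Temporal self-attention (single head,
width = feature count, softmax over time positions, no positional encoding)
follows, with residual add + layer normalization, a position-wise
feed-forward transform, and a second add + normalization. Global average
pooling over time and a linear softmax layer classify.

**MRCNN-LSTM.** Three branches with first-layer kernels 3 / 5 / 11
(small/medium/large receptive fields; the exact sizes are a design choice),
ReLU activations, and pooling of size 4 after convolutions 1 and 3 so the
concatenated sequence is short (~29 steps) before the single-layer LSTM
(hidden 64, forget-gate bias 1). The final hidden state passes through a
fully connected layer, dropout 0.5, and the softmax classifier.

Default filter counts are 32/64/64 per branch (unspecified by the protocol;
keeps the default model under 1 M parameters). `ModelSpec.scaled(k)`
divides widths by `k` for CPU-budget runs.

The tensor machinery is a small reverse-mode autodiff engine on numpy
float32 arrays (`eegmrcnn.nn`): convolution is evaluated as an im2col matrix
product, GELU uses the standard tanh approximation, gradients are verified
against central finite differences in the test suite.

## Training and evaluation

AdamW with decoupled weight decay 10⁻³ and cross-entropy loss (the optimizer
family is a design choice; a weight-decay hyperparameter strongly suggests
decoupled decay). The learning rate ramps linearly 5·10⁻⁵ → 10⁻³ over
epochs 0–20 and decays along a half-cosine to 5·10⁻⁴ at epoch 200 ("warmup
then gradual decay"; the interpolation shapes are design choices). The three
anchors are hit exactly and the schedule is continuous. No early stopping,
no inner validation split.

Five-fold cross-validation is stratified by class. The **fold unit**
defaults to epoch level, which matches the sample-count regime of
within-cohort studies but lets a subject's epochs appear in both train and
test — the accuracy it reports is partly subject re-identification, and the
package logs a warning saying so. Subject-level folds assign whole subjects
to folds and are the honest estimate of generalization to new people.

Metrics come from the confusion matrix with an explicit positive class
(default DD; note that the HC-as-positive convention also exists in the
literature, and `ConfusionCounts.swapped()` converts): accuracy, precision,
recall, and F1 = 2TP/(2TP+FP+FN). Zero-denominator cases return 0.0 and are
flagged in `MetricSet.undefined`. Across folds the SD uses the population
(n-fold) denominator.

## Scaled demo protocol

Training the full-width models on a 75-subject, 10-minute cohort is a
GPU-scale job. The package's validation runs therefore fix a scaled protocol
(`eegmrcnn.protocols`): 20 + 20 subjects, 48 s each (12 epochs per subject,
480 total), planted beta-band power ratio 1.8, filter widths divided by 8,
30 training epochs per fold for the headline run and 12 for multi-replicate
comparisons, ICA disabled (the demo cohorts are artifact-free). Under these
conditions the beta-band MRCNN-RSE reaches ~95 % epoch-level CV accuracy,
the theta band — where nothing is planted — stays at chance, and
shuffled-label controls fall in the 40–60 % chance band; the beta > theta
ordering is stable across seeds. These numbers characterize the pipeline on
synthetic data only and are not comparable to clinical accuracies.

## Numerical and I/O notes

* Epoch arrays are float64 end-to-end in preprocessing; models cast to
  float32.
* Filters are designed as second-order sections; impulse responses decay
  below 10⁻⁶ of peak within the test horizon for every canonical band.
* EDF export digitizes each channel to the full signed 16-bit range against
  physical limits *as encoded in the 8-character EDF header fields* (naive
  use of the unencoded limits skews the scale by more than a quantization
  step); round-trip error is bounded by about one step of the per-channel
  range (~1 % headroom included). Reading uses `mne.io.read_raw_edf`; files
  with mixed per-channel rates or truncated payloads are rejected outright.
* The array-on-disk format is a `.npy` array plus a JSON sidecar carrying
  subject id, group, rate, channel labels and provenance.

## Known limitations

* The numpy training loop is single-core; the full-width protocol at
  clinical scale is out of its practical reach (the architecture and
  protocol are exact, only widths/epochs are scaled in the demo).
* Epoch-level CV overstates clinical performance by construction; use
  subject-level folds for generalization claims.
* The ICA rejection rule is tuned to the generator's blink morphology;
  real recordings with muscle or electrode artifacts may need different
  criteria.
* No line-noise notch, re-referencing, or bad-channel interpolation.
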