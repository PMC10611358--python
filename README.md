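# eegmrcnn

A toolkit for EEG-based recognition of depressive disorder (DD) from **six
frontal channels** (Fp1, Fp2, F3, F4, F7, F8). It packages the full analysis
chain used in this line of research — resting-state EEG preprocessing,
rhythm-band decomposition, and two multi-resolution convolutional
classifiers — together with a synthetic cohort generator so the whole
pipeline can be exercised and validated without clinical recordings.

Intended users: researchers in EEG biomarker / computational psychiatry work
who want a reproducible, dependency-light reference implementation of this
kind of band-resolved deep-learning classification protocol.

## What it implements

**Preprocessing** (five stages, in order): downsampling 250 → 125 Hz with
anti-alias filtering; baseline correction (per-channel DC removal); ICA
artifact removal (FastICA with kurtosis-outlier and ocular-proxy rejection);
segmentation into non-overlapping 4 s epochs; and 4th-order Butterworth
bandpass filtering into theta (4–8 Hz), alpha1 (8–10 Hz), alpha2 (10–13 Hz),
beta (13–30 Hz) or the wide ranges 4–30 / 8–30 / 10–30 Hz.

**Classifiers**, operating on `epochs × 6 × 500` arrays:

* **MRCNN-RSE** — two parallel convolution branches with kernel ladders
  (4, 3, 3) and (10, 3, 3); each layer is conv → batch-norm → GELU, with max
  pooling after the first and third convolutions. The concatenated features
  pass through a residual squeeze-and-excitation block
  (`y = x + σ(W₂ ReLU(W₁ GAP(x))) ⊙ f(x)`), temporal scaled dot-product
  self-attention with two add-and-normalize stages, global average pooling
  and a softmax classifier.
* **MRCNN-LSTM** — three parallel convolution branches (ReLU) with kernels
  3, 5, 11; the concatenated feature sequence feeds an LSTM whose final
  hidden state is classified through a fully connected layer with dropout
  and softmax.

Both are built on a compact numpy autodiff engine included in the package
(`eegmrcnn.nn`), so there is no deep-learning framework dependency.

**Training protocol**: AdamW (decoupled weight decay 10⁻³), batch size 32,
up to 200 epochs, learning rate warming up linearly from 5·10⁻⁵ to 10⁻³
over 20 epochs and decaying along a cosine to 5·10⁻⁴. Evaluation is
stratified 5-fold cross-validation reporting accuracy, precision, recall and
F1 = 2TP/(2TP+FP+FN) as mean ± SD over folds, at either epoch level
(optimistic; a subject's epochs can appear on both sides of a split) or
subject level (leakage-free).

**Synthetic cohorts**: each channel is `1/f^α` background noise plus
band-limited oscillations whose power ratio between the two groups is
controlled per band (a beta-band ratio emulates the beta-power alteration
reported in DD), with per-subject gain variation and optional stereotyped
ocular artifacts for the ICA stage. Fixed seeds give bit-identical cohorts.

## Worked example

Classify a synthetic cohort (20 + 20 subjects, 48 s each, beta-band power
ratio 1.8 between groups) in the beta and theta bands:

```python
from eegmrcnn import BANDS, PipelineConfig, TrainConfig, cross_validate, generate_cohort
from eegmrcnn.preprocess import bandpass, preprocess_cohort
from eegmrcnn.protocols import demo_cohort_spec, demo_model_spec
from eegmrcnn.train_eval import format_report_table

cohort = generate_cohort(demo_cohort_spec(seed=1))
broadband = preprocess_cohort(cohort, PipelineConfig(use_ica=False))
reports = {}
for tok in ("beta", "theta"):
    epochs = bandpass(broadband, BANDS[tok])
    reports[tok] = cross_validate(epochs, demo_model_spec(), TrainConfig(seed=1),
                                  n_epochs=12)
print(format_report_table(reports))
```

prints (about three minutes on one CPU):

```
Data                    Accuracy                  F1           Precision              Recall
--------------------------------------------------------------------------------------------
beta               94.58 ± 2.50%       94.52 ± 2.58%       95.42 ± 3.02%       93.75 ± 3.95%
theta              52.50 ± 5.91%       57.51 ± 6.04%       51.87 ± 4.74%       64.58 ± 8.01%
```

The planted group difference lives only in the beta band, so the beta-band
classifier separates the groups well while the theta-band classifier stays
at chance — the band-resolved analysis recovers where the discriminative
physiology sits.

The same workflow is available from the shell:

```sh
eegmrcnn simulate --config cohort.yaml --out raw/ --seed 1
eegmrcnn preprocess --in raw/ --out pre/ --band beta --no-ica
eegmrcnn train --data pre/ --arch mrcnn_rse --folds 5 --seed 1 --out run/
eegmrcnn evaluate --run run/ --report report.json
eegmrcnn run --out demo/            # end-to-end with a small demo config
```

## Layout

```
src/eegmrcnn/
  synth.py        synthetic two-group EEG cohorts
  preprocess.py   five-stage preprocessing pipeline
  models.py       MRCNN-RSE and MRCNN-LSTM architectures
  train_eval.py   schedule, k-fold CV, confusion-matrix metrics
  nn/             numpy autodiff engine, layers, AdamW
  edf.py          EDF read (via mne) / write
  experiment.py   end-to-end orchestration from a YAML config
  cli.py          command-line interface
  protocols.py    the scaled demo study conditions
docs/methods.md   model and design notes
```

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
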