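# pcgstack

Detection of heart failure with preserved ejection fraction (HFpEF) from
phonocardiogram (PCG) recordings, via gammatone spectrograms, gray-level
texture analysis, and an AUC-weighted heterogeneous stacking ensemble.

HFpEF is the diastolic-dysfunction phenotype of chronic heart failure; it
is hard to screen for because the ejection fraction is, by definition,
normal. Heart sounds carry diastolic information (S1/S2 morphology,
low-frequency extra sounds), so a cheap digital stethoscope recording is
an attractive screening signal. `pcgstack` implements a complete,
reproducible pipeline for binary non-HF vs HFpEF classification from
single-channel PCG audio, for researchers in biomedical signal processing
who want to study or extend that pipeline on their own data or on
synthetic data.

## The model

Each ~10-s recording is conditioned (10–1000 Hz Butterworth band-pass, a
zero-phase FIR notch at 50 Hz, optional SVD+wavelet denoising,
resampling to 2205 Hz, z-scoring) and rendered as a **gammatonegram**:
the per-channel short-time RMS of a gammatone filterbank with impulse
response

    g(t, f_c) = a t^{n-1} e^{-2 pi b t} cos(2 pi f_c t + phi),   t >= 0

with order n = 4, ERB-rate-spaced center frequencies f_c, and
Glasberg–Moore bandwidths b = 1.019 ERB(f_c) — narrow channels at the low
frequencies where heart sounds live.

From the log-compressed spectrogram image two feature families are
extracted:

* **Texture** — the image is quantized to N_g = 32 gray levels and the
  four classical gray-level matrices are built (GLCM, GLRLM, GLSZM,
  GLDM); 24 + 16 + 16 + 14 = **70 IBSI-style scalar features** are
  computed, with GLCM/GLRLM averaged over the four 2-D directions.
* **Deep** — a pluggable backbone interface (ResNet50 / DenseNet121 /
  InceptionResNetV2 as configuration; a deterministic seeded
  random-projection convolutional backbone as the desk-scale default)
  followed by PCA.

Four base learners produce calibrated class posteriors P_mu: one RFE-SVM
on the texture features and three PCA + random-forest models on the deep
features. With h_mu the pooled out-of-fold AUC of learner mu on the
training set, the ensemble weights and meta-learner inputs are

    w_mu = h_mu / sum_nu h_nu,        zeta_mu = w_mu P_mu,

and an MLP with hidden layers (256, 128, 64) is trained on zeta as the
meta-learner. Evaluation follows a subject-stratified 7:3 split with
5-fold out-of-fold stacking (no segment of a subject ever crosses a
fold or split boundary), a full metric panel with DeLong AUC confidence
intervals, DeLong tests between correlated ROC curves, and optional
repetition over fresh splits. Gaussian-process Bayesian optimization
with expected improvement is included for hyperparameter tuning.

## Worked example

```bash
python examples/05_train_ensemble.py
```

simulates 24 subjects (12 per class, 3 five-second segments each) with a
strong synthetic class effect, trains the full stack, and prints:

```
test AUC   : 1.000  (95% CI [1.000, 1.000])
accuracy   : 1.000   sensitivity: 1.000   specificity: 1.000
precision  : 1.000   F1: 1.000
OOF AUCs   : [0.991, 1.0, 1.0, 1.0]
weights    : [0.248, 0.251, 0.251, 0.251]
base test AUCs: {'texture': 1.0, 'deep_0': 1.0, 'deep_1': 1.0, 'deep_2': 1.0}
```

The OOF AUCs are each base learner's out-of-fold AUC on the training
side; their normalization gives the ensemble weights (summing to 1), and
the test panel is computed on held-out subjects only. With a large
simulated effect every pathway separates the classes, so the ensemble
sits at AUC 1.0; `examples/06_compare_strategies.py` contrasts voting,
plain stacking, and weighted stacking on identical base learners, and
the other examples walk through each stage in isolation.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end-to-end from scratch: it simulates a grouped
synthetic dataset (20 subjects per class, 5 segments each), runs
preprocessing, spectrograms, both feature pathways, out-of-fold
stacking, and held-out evaluation, prints the resulting metric panel,
and writes the results JSON to `--out`. The `--seed` argument drives
every source of randomness, so reruns are bit-reproducible.

## Layout

```
src/pcgstack/
  simulate.py       synthetic grouped PCG datasets (WAV + CSV manifest I/O)
  preprocess.py     band-pass, notch, SVD+wavelet denoise, resample, z-score
  gammatone.py      ERB filterbank, gammatonegram, image export
  texture.py        GLCM/GLRLM/GLSZM/GLDM + 70-feature panel
  deep_features.py  backbone interface + desk-scale default, PCA
  learners.py       RFE-SVM and PCA-RF base learners, Platt calibration
  ensemble.py       AUC weights, OOF stacking, MLP meta-learner, baselines
  evaluation.py     AUC/metrics, DeLong test and CIs, subject splits
  bayesopt.py       GP + expected-improvement hyperparameter search
  pipeline.py       end-to-end wiring, config, caching, provenance
examples/           one narrative script per capability
docs/methods.md     model assumptions, defaults, numerical conventions
```
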