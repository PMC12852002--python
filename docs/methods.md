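# Methods

This note records the scientific and numerical choices behind `pcgstack`:
what each stage assumes, which defaults matter and why, what the
synthetic-data generator does and does not emulate, and the conventions
used for degenerate inputs.

## Signal conditioning

The chain is band-pass -> notch -> (optional) denoise -> resample ->
z-score, with all filtering done at the original sampling rate.

* **Band-pass**: 4th-order Butterworth, 10–1000 Hz, applied
  forward–backward (`sosfiltfilt`). Zero-phase filtering is used so the
  relative timing of S1 and S2 — which the spectrogram texture encodes —
  is not distorted by group delay. The order is a package choice; the
  band edges are the physiological PCG band.
* **Notch**: a linear-phase FIR band-stop centred at the 50 Hz mains
  frequency (design half-width 6 Hz, 2401 taps, Hamming window), applied
  as a centred convolution so the symmetric taps give a net zero-phase
  response. Measured behaviour at 4410 Hz: >= 40 dB attenuation at
  50 Hz, < 0.1 dB ripple at 40/60 Hz. An LMS-adaptive variant (two-weight
  canceller with quadrature references) is available behind
  `adaptive=True`; only the fixed filter is part of the tested surface
  because no adaptation rule is canonical.
* **Denoise** (`denoise_svd_wavelet`): Hankel embedding with window
  len/10 (the fs/10 convention at 1 s of signal), retaining leading
  singular components to 95% of squared-singular-value energy, then
  reconstruction by anti-diagonal averaging; followed by a 5-level
  periodized db4 wavelet shrinkage with a soft universal threshold
  sigma sqrt(2 ln N), sigma estimated from the finest-detail median
  absolute deviation. The DWT is implemented in-package (no wavelet
  library is available in the runtime); its one-level round-trip is exact
  to ~1e-12. Denoising is **off by default in the pipeline profile**: at
  10 s x 4410 Hz the Hankel SVD costs seconds per recording, and the
  synthetic data's white-noise floor is already handled by the later
  stages. It is fully tested (SNR gain at 5 dB input SNR; correlation
  >= 0.99 on clean input) and can be enabled per config.
* **Resample + z-score**: polyphase resampling to 2205 Hz
  (`padtype="line"` so constant/linear edges do not ring), then exact
  z-scoring. A constant signal raises a degenerate-input error.

## Gammatonegram

Center frequencies are spaced uniformly on the ERB-rate scale
(21.4 log10(4.37e-3 f + 1)) over 20–1000 Hz, 64 channels by default —
matching the band-pass and giving dense resolution in the 30–90 Hz
S1/S2 region. Bandwidths are 1.019 ERB(f_c) (Glasberg–Moore), order
n = 4, a = 1, phi = 0. Channels are realized as causal FIR kernels: the
analytic impulse response truncated where its gamma envelope falls below
1e-5 of peak. Per-channel frame RMS over 25 ms frames with 10 ms hop
forms the channels x frames matrix; entries are non-negative and scale
linearly with the input.

Image export: amplitude dB (20 log10 relative to the matrix maximum),
clipped to the top 60 dB, min–max scaled to [0, 1], bilinear resize.
The pipeline profile uses 64 x 64 images (texture statistics at N_g = 32
are well-populated at that size and every stage stays CPU-cheap);
224 x 224 is the default for the standalone `to_image`, matching common
CNN input sizes. An all-zero or constant matrix maps to an all-zero
image (min–max scaling has no spread to normalize).

## Texture features

The image is quantized by equal-width binning of [min, max] into
N_g = 32 levels (fixed bin *count*, because the image is already
normalized to [0, 1]; a constant image maps to all-1 without error).
Matrices:

* GLCM: distance 1, four directions, symmetric, normalized to sum 1.
* GLRLM: maximal constant-level runs along each of the four directions.
* GLSZM: 8-connected constant-level zones (direction-free).
* GLDM: dependence = number of neighbors within Chebyshev distance 1
  whose level differs by <= delta, delta = 0.

Coordinates are (x, y) = (column, row) with the origin top-left, y
increasing downward, everywhere.

Features: 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM = 70, the de-facto
standard radiomics panels; GLCM and GLRLM feature values are averaged
over the four directions, which makes them invariant to 90-degree image
rotation. In the GLDM feature formulas the dependence size enters as
d + 1 (the reference pixel counts as part of its own dependence group),
keeping small-dependence emphases finite at d = 0. Degenerate
conventions, chosen so every feature is finite on every input:
correlation and the two information measures of correlation are 0 when a
marginal variance/entropy vanishes; the maximal correlation coefficient
is 0 when fewer than two gray levels are occupied.

## Deep features

The backbone interface accepts ResNet50 / DenseNet121 /
InceptionResNetV2 specs (with Adam fine-tuning settings — batch 16,
120 epochs, learning rate 1e-4, early stopping — carried as
configuration), but those need pretrained weights and a deep-learning
runtime; requesting one raises an explicit unavailable-backbone error.
The tested default, `desk_default`, is a seeded random-projection
convolutional stand-in: 16 zero-mean 5x5 filters, absolute-value
rectification, 4x4 grid average pooling, and a seeded random projection
to `output_dim` (64). It is deterministic, cheap, and sensitive to
band-energy structure — sufficient to exercise PCA, the random forests,
and the stacking logic. Three different seeds stand in for the
architectural diversity of the three CNNs. Conclusions from green tests
therefore cover the ensemble mechanics, not the representational power
of actual pretrained CNNs.

PCA is implemented as centered SVD keeping the minimal component count
whose explained variance reaches the requested fraction (default 0.95);
variance_fraction = 1.0 keeps exactly the numerical rank.

## Base learners and calibration

* Texture pathway: features are standardized (train statistics only),
  ranked by linear-SVM weight magnitudes under RFE (removing 10% of
  features per iteration — the elimination order makes selected sets
  nested across n_select), and the final RBF SVM with probability
  outputs is trained on the selected 10 features.
* Deep pathway: PCA fitted on training features only, then a random
  forest (300 trees in the pipeline profile; 500 standalone default).

Calibration is a Platt sigmoid fitted by logistic regression of held-out
labels on the raw posterior. The fitted slope/intercept are rescaled so
|a p + b| <= 30 on [0, 1]: beyond that the sigmoid saturates in double
precision, creating ties that would perturb AUC; inside it the map is
strictly monotone, so calibration provably preserves ranking and AUC.
In the ensemble, calibration is fitted on the pooled out-of-fold
posteriors.

## Stacking ensemble

Training folds are subject-grouped and label-stratified
(StratifiedGroupKFold, K = 5). Every training sample receives exactly
one out-of-fold posterior per base learner from a model that saw no
segment of its subject — a memorizing learner scores AUC 0.5 out-of-fold,
which is the package's leakage canary. "Validation AUC" h_mu for the
weights is the pooled out-of-fold AUC (all training data, no extra
holdout); weights are recomputed per split. The meta input uses only
p(+1) per learner (p(−1) is redundant by complementarity), scaled
columnwise by the weights. The meta-learner is an MLP (256, 128, 64),
ReLU, Adam, max 500 epochs with early stopping on an internal 10% split,
seeded. Baselines sharing the same fitted base learners: soft voting
(mean calibrated posterior) and plain stacking (meta-learner on
unweighted posteriors); with equal h_mu the weighted meta input equals
the plain input scaled by 1/mu.

Classification threshold is fixed at 0.5 on the calibrated ensemble
posterior; metrics are segment-level.

## Evaluation statistics

AUC is the Mann–Whitney statistic with ties counted 1/2. DeLong
placement values give the variance of one AUC and the covariance of two
correlated AUCs; the test statistic is Delta AUC over its standard
error against a standard normal, and the 95% CI is the normal
approximation clipped to [0, 1]. A class with a single member
contributes zero spread (no variance information). Identical score
vectors short-circuit to p = 1; zero variance with a nonzero difference
raises a degenerate-case error. Subject-stratified splitting draws
round(0.7 n) subjects per class into training; because segment counts
per subject may vary, the 7:3 ratio is exact at subject level, not
necessarily at segment level.

## Bayesian optimization

Inputs are encoded into the unit cube (log-scaled where flagged,
integers by rounding, categoricals one-hot); losses are standardized. A
zero-mean GP with squared-exponential kernel, fixed length-scale 0.2 in
encoded units, and 1e-8 jitter gives the posterior; acquisition is
closed-form expected improvement for minimization, maximized over 512
random candidates with L-BFGS-B refinement from the top 8. The loop is
Latin-hypercube initialization (n_init = 5) then EI proposals,
deterministic per seed. A failing objective is recorded at the worst
observed loss and flagged rather than aborting the run. Per-fold
independent tuning is possible by calling the optimizer inside a fold
loop; the provided examples tune globally, which is the affordable
default at desk scale. The default loss is 1 − validation AUC.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not cardiac hemodynamics. Per cardiac cycle: a Gaussian-windowed S1 tone
(45 Hz, 45 ms width) and an S2 tone (70 Hz, 30 ms, amplitude 0.8) at a
systolic offset of 0.35 cycles; heart rate 70 bpm by default; white
noise with sd 0.05; per-subject random effects (log-normal amplitude,
timing-jitter scale, ±2 Hz frequency offset) so subject-grouped
splitting is meaningfully tested. The case class adds a low-frequency
extra component after S2 (25 Hz, amplitude 0.35 per unit effect size —
an S3-gallop-like feature consistent with diastolic dysfunction) and
shifts the S2 frequency by +12 Hz per unit effect size; at effect size 0
the two class-conditional distributions are identical by construction.
Default scale: 40 subjects per class, 5 segments per subject, 10 s at
4410 Hz (so the downsample step is real). What a green end-to-end test
establishes: the pipeline recovers a band-energy/texture class
difference and stays at chance when there is none. What it does not
establish: performance on real auscultation audio, murmurs, arrhythmia,
sensor artifacts, or class differences more subtle than band energy.

## Reproducibility

Every stochastic component (simulation, fold assignment, SVM/RF/MLP
seeds, optimizer) is driven by explicit seeds recorded in the result's
provenance block together with the config hash and split membership.
Features are cached keyed by (upstream-config hash, content hash of the
audio), so cache hits cannot alias datasets that merely share naming.

## Known limitations

* The pretrained-CNN pathway is interface-only here; the desk backbone
  is a stand-in, and reported synthetic AUCs say nothing about clinical
  performance.
* The GP uses a fixed kernel length-scale rather than marginal-likelihood
  fitting; adequate for low-dimensional tuning, not for high-dimensional
  spaces.
* The adaptive-notch and denoiser parameters are engineering defaults;
  neither has a canonical published setting for PCG.
* Heart-sound segmentation (S1/systole/S2/diastole) is deliberately not
  performed; the pipeline operates on whole segments.
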