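# Methods

## Problem

Plants exposed to sub-lethal doses of herbicides (butachlor, quinclorac)
or heavy metals (cadmium, copper) often show no visible symptoms, yet the
stressor type matters for intervention. Two imaging techniques capture
complementary physiology: hyperspectral imaging yields a VIS/NIR
reflectance spectrum per organ (pigments, structure, water status), and
chlorophyll-fluorescence imaging yields an induction kinetic curve
(photosystem-II activity). This package classifies a plant into five
treatment classes — control (CK), Cd, Cu, butachlor (DCA), quinclorac
(ELK), coded 0–4 — from up to four 1-D inputs per plant: leaf and stem
VIS/NIR reflectance (396 bands, 454–957 nm) and leaf and stem
fluorescence kinetics (286 timepoints).

## Preprocessing

Raw hyperspectral cubes are calibrated to reflectance per pixel,

    I = (I_raw − I_black) / (I_white − I_black),

with dark-current and white-reference images; the operation requires
`I_white − I_black > 0` wherever used and is affine in `I_raw`. Pixel
spectra inside an organ mask are individually denoised with a
Daubechies-8 discrete wavelet transform at 3 decomposition levels, then
averaged into one curve per organ. Denoise-then-average is implemented
exactly in that order: with nonlinear thresholding it is not equivalent
to averaging first (an `average-then-denoise` fast path exists but is
not the default).

Wavelet thresholding uses the soft universal rule: the noise scale is the
median absolute deviation of the finest-level detail coefficients divided
by 0.6745, and the threshold is `sigma * sqrt(2 ln n)`. Boundary handling
is symmetric extension. These two choices are the common chemometrics
defaults; both are recorded in `WaveletSpec` so they can be swapped. A
consequence of the eight vanishing moments is that constants and
low-order polynomials pass through unchanged (up to boundary effects),
which the tests exploit as exact oracles.

Reflectance curves are truncated to the closed window [454, 957] nm
(instrument noise dominates outside it), and every curve — reflectance
and kinetic — is finally maximum-normalized (divided by its own maximum).
Wavelet denoising is applied to reflectance pixel spectra only; kinetic
curves are ROI-averaged and normalized but not wavelet-filtered, since
per-pixel spectral denoising is a reflectance-specific step in this
pipeline.

## The base classifier (CNN-S)

One 1-D input vector `X` of length `d` passes through:

1. **Attention gate** `Y = ReLU(W1 · ReLU(W2 · X + b1) + b2) ⊙ X`, with
   `W2 ∈ R^{h×d}`, `W1 ∈ R^{d×h}`. The gate activation is ReLU (not a
   sigmoid), so gates are unbounded above and zero-propagating:
   `X_i = 0 ⇒ Y_i = 0`, and each output coordinate is zero or keeps the
   input's sign. The hidden width defaults to `h = d`. `b2` is
   initialized to ones so the gate starts approximately open (identity
   map) and the rest of the network can train from a sensible operating
   point.
2. **Convolution block**: three 1-D convolutions (kernel 3, stride 1,
   ReLU, same-length zero padding) with one max-pool (size 2, stride 2)
   after the first. Channel counts default to 16/32/32 — a deliberately
   shallow design for few-sample spectral data; they are configurable.
3. **Dense head**: dense layers of 512, 128 and 5 units (ReLU on the
   first two), softmax output over the five classes. Batch normalization
   precedes every convolution and dense layer. The 128-unit activation
   feeding the final dense layer is the "deep feature" reused by the
   fusion models.

The loss is softmax cross-entropy. All layers, gradients and the SGD
optimizer are implemented in NumPy with float32 arithmetic; backward
passes are verified against central-difference gradients in the tests.

## Fusion levels

Five modality subsets ("Fusion 1–5") are supported: both reflectance
curves; both kinetic curves; the leaf pair; the stem pair; all four.
Concatenation order is fixed: l_visnir, s_visnir, l_fkc, s_fkc.

* **Low level**: the selected raw vectors are concatenated (e.g. 1364
  features for all four) and fed to a single CNN-S.
* **Middle level** (end-to-end): one CNN-S trunk per modality produces a
  128-d feature `F_i`; a trainable per-branch map with ReLU,
  `ReLU(W_i · F_i)`, is concatenated over branches and classified by a
  dense softmax head; one cross-entropy on the fused output trains
  everything jointly. The branch weights are full 128×128 linear maps
  (matching the matrix-product reading of the fusion expression); a
  scalar-weight mode is available behind a flag.
* **High level** (end-to-end decision fusion): one complete CNN-S per
  modality outputs probabilities `y_i`; their concatenation (length 5m)
  feeds a dense layer with five neurons and softmax producing `y_F`. The
  joint loss

      L = ce(y, y_F) + Σ_i ce(y, y_i)

  drives the fused head and every submodel simultaneously, keeping the
  fused inputs genuine probability distributions. Gradients flow through
  the concatenation into the submodels (full end-to-end training).
  Cross-entropies on probabilities floor them at 1e-12. The decision
  head is initialized at probability averaging (stacked identity blocks
  divided by m): the model starts as the two-stage average-probability
  baseline and training refines the combination — without this the head
  must first undo a random mixture of near-saturated probability
  vectors, which is slow at small step counts.
* **Two-stage baselines**: middle level with independently trained,
  frozen extractors plus a fresh CNN-S on the concatenated 128m-d
  feature table (m + 1 trained models in total), and high level as plain
  averaging of separately trained submodels' probability vectors with
  argmax (ties to the smallest class index).

## Training protocol

Minibatch SGD, batch 128, 500 epochs by default; learning rate 0.005
decayed to one tenth every 100 epochs (`lr(e) = 0.005 · 0.1^⌊(e−1)/100⌋`,
1-based epochs). The optimizer is plain SGD because the schedule is the
only optimization detail the protocol fixes; an adaptive method would
override it (momentum is available behind config, off by default). After
every epoch the training and validation accuracies are recorded and the
parameter snapshot with the highest validation accuracy is kept (earliest
epoch on ties; selection by validation loss is available behind a flag).
Test accuracy is computed once, on the selected snapshot. Partial final
batches are kept.

Batch-norm inference statistics are re-estimated after every epoch by a
calibration pass over the training set that replaces the exponential
running averages with exact population moments at the current
parameters. With hundreds rather than thousands of training samples an
epoch has only a few batches, and exponential averages then lag the
moving parameters badly enough to corrupt inference-mode accuracy —
especially under the joint decision-fusion loss, whose submodel terms
keep a persistent gradient on structurally confusable classes. The
calibration pass makes inference-mode outputs on the training set equal
training-mode outputs exactly (tested).

Datasets are split 4:1:1 into train/validation/test, stratified per
class: a class of n samples sends ⌊n/6⌋ to validation, ⌊n/6⌋ to test and
the remainder to training (classes with fewer than 3 samples go entirely
to training, with a warning). The floor rule is one of several
consistent readings of a 4:1:1 ratio; exact reproduction of any
particular historical table of split sizes is not guaranteed.

## Synthetic data generator

No public dataset of this kind exists, so the generator is a first-class
module that emulates the statistical structure the fusion method assumes,
with analytically known class templates:

* **Reflectance**: a smooth vegetation baseline (low visible reflectance,
  green peak near 550 nm, chlorophyll absorption dip near 670 nm,
  sigmoidal red edge to a NIR plateau of 0.45 for leaves, 0.38 for
  stems) plus two class-specific Gaussian bumps (width 20 nm, amplitudes
  ±0.025–0.035 scaled by `class_effect_scale`). Stems shift bump centers
  by 6 nm and scale amplitudes by 0.9 — organs are similar but not
  identical.
* **Kinetics**: `F(t) = F0 + A · (1 − e^{−kr t}) · (s + (1−s) e^{−kd t})`
  on a unit time axis — a saturating rise from F0 = 0.2 toward
  F0 + A ≈ 1.0 followed by exponential relaxation to a steady-state
  fraction s = 0.55. Classes modulate A, kr and kd. Timepoints are a
  uniform index; no claim is made about real induction-protocol timing.
* **Noise**: i.i.d. Gaussian with `noise_sd`, clipped at zero (both
  quantities are physically nonnegative). Clipping is the only
  non-Gaussian feature of the noise.
* **Complementarity** `c ∈ [0, 1]`: class 4's reflectance template is
  linearly morphed onto class 3's and class 2's kinetic template onto
  class 1's. At `c = 1` the DCA/ELK pair is separable only through
  kinetics and the Cd/Cu pair only through reflectance, so any single
  modality is structurally capped near 80% balanced accuracy while the
  four together identify every class — the regime where fusion provably
  beats any single source.

Defaults: per-class counts (240, 360, 360, 268, 358) mirroring the
emulated experiment's treatment groups; `class_effect_scale = 1.0`;
`noise_sd = 0.01` (about a third of the bump amplitude per band — enough
within-class spread that classification is non-trivial without
swamping the class signal); `complementarity = 0.5` as a neutral middle.

What the generator does **not** emulate: pixel-level image structure
(curves are already ROI-averaged), correlated (smooth) instrument noise,
concentration sub-groups within a treatment, batch/day effects, or any
biophysically derived radiative-transfer or photosystem-II model.
Passing benchmarks on this data therefore demonstrates that the
architectures and training protocol recover the kinds of class structure
they were designed for — including cross-modal complementarity — not
that they reach any particular accuracy on real plants.

## Benchmark scales and numerical choices

The desk-scale benchmark used by the acceptance tests and the
reproduction script runs at 72 samples per class (48 train / 12
validation / 12 test per class) for 50 epochs, three seeds for the
complementarity comparison — sizes chosen so the full suite retrains
every model family from scratch in minutes on one CPU core. At these
sizes the learning-rate schedule never decays (50 ≤ 100 epochs), which
matches the protocol's constant-rate first phase. Benchmark noise levels:
`noise_sd = 0.005` for the complementarity benchmark and 0.003 for the
"all families learnable" check on redundant (complementarity 0) data.

Other numerical choices: He (fan-in) initialization for dense and
convolution weights; attention gate weights scaled by an extra 0.1 with
`b2 = 1` (near-identity start); batch-norm epsilon 1e-5; cross-entropy
probability floor 1e-12; max-pool drops a trailing odd element;
prediction argmax ties resolve to the smallest class index; the SVM grid
search (C and gamma over 10^−8…10^8 by decades, 289 pairs) selects on
validation accuracy with ties to the smallest C, then the smallest
gamma. All randomness flows through explicit integer seeds; two runs
with the same seeds are bitwise identical in single-threaded execution.

## Known limitations

* The NumPy training stack is single-threaded-CPU oriented; it is
  intended for datasets of a few thousand samples, not for large-scale
  training.
* The attention gate follows the ReLU-gate formulation exactly; it is
  unbounded above, which can amplify features (unlike sigmoid gating).
  With the near-identity initialization this has been benign in
  practice.
* Two-stage middle-level fusion retrains a full CNN-S on 128m-d
  features; no dimensionality reduction is applied between stages.
* The ENVI reader covers plain BSQ/BIL/BIP files with standard headers
  only.
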