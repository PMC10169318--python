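# Methods

## Problem and models

The package classifies grayscale transmission-electron-microscopy (TEM)
images of renal biopsies by whether an electron-dense granule — a dark,
osmiophilic immune-complex deposit — is present (Positive) or absent
(Negative). Three classifiers are implemented and compared:

1. **Conventional residual network.** A 50-layer-style backbone (7×7/2 stem
   with 3×3/2 max-pool, then four stages of bottleneck residual blocks with
   filters [64,64,256]×3, [128,128,512]×4, [256,256,1024]×6,
   [512,512,2048]×3). The residual blocks follow the two standard forms:
   identity blocks `H(x) = ReLU(F(x,{Wi}) + x)` and convolutional blocks
   `H(x) = ReLU(F(x,{Wi}) + Ws x)`, with `F` the 1×1→3×3→1×1 bottleneck
   (conv + batch-norm, ReLU after the first two). Classification is global
   average pooling of the stage-5 map followed by one fully connected layer
   with softmax over the two classes, trained with Adam on cross-entropy.

2. **Skip-architecture extractor + SVM.** The same backbone, but the
   classifier consumes the concatenation of the *stage-2* feature map
   (fine, local detail; 56×56×256 at full scale) and the *stage-5* map
   (coarse, global context; 7×7×2048), flattened to a single vector of
   length 56·56·256 + 7·7·2048 = 903,168. A soft-margin SVM solves the dual

       max W(α) = Σᵢ αᵢ − ½ Σᵢⱼ αᵢαⱼ yᵢyⱼ K(xᵢ,xⱼ)
       s.t. Σᵢ αᵢyᵢ = 0,  0 ≤ αᵢ ≤ C

   and predicts with f(x) = Σᵢ αᵢyᵢ K(xᵢ,x) + b.

3. **Stacking multi-model.** A fixed-topology feed-forward network — two
   input neurons (the two base models' scores in (0,1)), one hidden layer,
   one sigmoid output — trained by full-batch gradient descent on
   cross-entropy over a dedicated stacking cohort. The rationale is the
   usual one for stacking: the two base models make partially independent
   errors, and a small nonlinear meta-learner can learn when to trust which.

## Experimental protocol

The corpus is split into three pairwise-disjoint, class-stratified cohorts
(374 / 352 / 184 for a 910-image corpus; 60 / 40 / 40 at desk scale):
cohort 1 trains both base models, cohort 2 is scored by the trained base
models and those scores train the combiner, cohort 3 is held out for the
final three-way comparison. Disjointness is asserted on every run, and the
emitted report is audited automatically: every table metric must be exactly
recomputable from the emitted confusion matrices.

Evaluation uses the confusion-matrix suite — recall TP/(TP+FN), precision
TP/(TP+FP), F1 = 2PR/(P+R), accuracy (TP+TN)/N — plus the ROC curve
(FPR = FP/(FP+TN) vs TPR = TP/(TP+FN), swept over every distinct score
threshold with "Positive when score ≥ threshold", so tied scores share one
point) and its trapezoidal area (AUROC). Table output is rounded to two
decimals; raw values are always kept alongside. Zero-denominator metrics
raise instead of returning 0, so degenerate evaluation sets are loud.

## Implementation choices

**Forward-only NumPy backbone.** The backbone is a forward-pass
implementation: im2col convolutions contracted with one BLAS call per
layer, "same" padding (extra pixel on the high side) chosen so a 224×224
input lands exactly on the printed 56/28/14/7 stage grids, and batch-norm
folded into per-channel affine maps with frozen statistics. Feature
extraction is therefore deterministic to the bit for fixed weights. A full
224×224 forward pass takes ≈0.3 s on one CPU core. There is no autodiff:
the trainable parts are exactly those with hand-computable gradients — the
softmax head (linear layer; softmax-cross-entropy gradient) and the 2-H-1
combiner (one hidden layer; explicit backprop).

**Initialisation.** No pretrained weights ship with the package
(`init="pretrained"` raises, advising random init). Random init is He
normal for convolutions with the *near-identity residual* convention: the
last batch-norm of every residual branch starts with scale 0.2, so each
block initially perturbs rather than overwrites its input. With ~16 stacked
blocks this keeps activation variance controlled and preserves input signal
in the frozen features; an 8-seed sweep of the desk-scale protocol showed
mean validation F1 of the SVM model rising from 0.76 to 0.88 (worst seed
0.46 → 0.65) compared with plain He init.

**Head training.** The backbone stays frozen while the softmax head trains
(transfer-learning style). `TrainConfig` defaults to learning rate 1e-5 —
the appropriate rate *for fine-tuning a pretrained backbone*, kept as the
stated default. When the head is trained from scratch on frozen random
features (the only path without pretrained weights) the pipeline uses Adam
1e-2 with mini-batches of 4 for its default 10 epochs: a 10-epoch budget on
a few dozen images is very few optimiser steps, and the larger step size
with smaller batches is what lets a linear head converge in that budget.

**SVM.** Optimisation is delegated to a mature SMO solver
(scikit-learn SVC); the fitted model is re-expressed in dual quantities
(support vectors, multipliers α with 0 ≤ α ≤ C and Σαy = 0, bias) and the
decision function is evaluated by this package's own kernel expansion —
tests cross-check the two routes and compare the dual objective against a
brute-force quadratic-programming oracle on tiny problems. Kernel default
is RBF with the γ = 1/(d·var) heuristic and C = 1 (linear and polynomial
selectable); features are standardised per dimension on the training cohort
only, because the raw concatenated activations span very different scales.
For stacking, the signed decision value is mapped through a logistic link
to (0,1).

**Combiner.** Hidden width defaults to 4 sigmoid units — the smallest width
that comfortably realises nonlinear two-input logic (the AND of the rounded
inputs is a test case) — trained full-batch (rate 1.0, ≤500 epochs, early
stop on loss plateau). Seeded init makes retraining bit-reproducible.

## Synthetic data

The clinical TEM corpus is not available, so a generator produces
micrograph-like images: a Gaussian-filtered band-limited noise background
around mid-gray (texture correlation length 16 px at 224 px frame), a few
faint curvilinear membrane strokes, and — in positives only — 3–8
non-overlapping dark elliptical deposits (semi-axes 4–10 px, intensity
multiplied by 1 − drop with drop = 0.5, rims feathered by a 1 px Gaussian)
scattered along a simulated membrane curve, plus Gaussian sensor noise
(σ = 0.02 gray levels). A `tiny` preset scales the frame to 64 px
(deposits 2–5 px, counts 2–5) to match the tiny backbone input. Per-sample
seeds derive from (master seed, pair index, label), so datasets are
bit-identical across runs and platforms and independent of generation
order. Positives and negatives differ *only* by the painted deposits.

What this emulates — and does not. The generator reproduces the decisive
visual cue (dark, compact, high-density deposits on textured gray
background) and a learnability guarantee: a trivial dark-component
threshold rule reaches ≥95% at low noise, so any reasonable learner has
signal to find. It does not model electron optics, staining variability,
deposit ultrastructure, subepithelial vs mesangial localisation, or
patient-level correlation; a model that performs well here is validated as
machinery (shapes, training, stacking, metrics), not as a clinical
classifier. The study's real-data AUROCs are consequently not reproducible
and are not targets of any test.

## Numerical and degenerate-input conventions

- Flatten order for the SVM feature vector is channel-last row-major on
  (H, W, C), stage 2 first, and is part of the model contract.
- Resize is bilinear; grayscale inputs are replicated to three channels at
  the backbone input.
- Classification ties (score exactly at threshold) resolve Positive.
- Single-class training sets, length mismatches, non-finite features and
  unbuilt/untrained components raise typed errors (`TrainingError`,
  `ValidationError`, `StateError`).
- Contradictory duplicate training points drive all multipliers to the
  box bounds (verified against the 2-variable dual by hand).

## Problem sizes

Default test and acceptance runs use the tiny scale: 64×64 input, channels
divided by 8, cohorts 60/40/40 — the topology (stage count, block counts,
stage-2 skip) is identical to full scale, so every structural property
tested at tiny scale transfers. Full scale is exercised for the shape
contract (one forward pass) and available throughout the API.

## Known limitations

- No fine-tuning of convolutional weights (forward-only backbone); the
  conventional model is accordingly a frozen-feature baseline, which is
  consistent with its role as the weaker comparator.
- Desk-scale results vary noticeably with the data seed at n = 40
  validation images; conclusions from single seeds are indicative only.
- The SVM's kernel family, C, and feature scaling in the original study
  are unreported; defaults here are field-standard choices, not a
  reconstruction.
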