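# Methods

## Architecture family

The family is the classic four-level U-Net with one knob: a global filter
reduction factor α applied uniformly to every stage before training
(structured kernel pruning — whole filters are removed, no sparse masks).
Encoder level *i* holds `64/α · 2^(i-1)` filters; the latent level doubles
the deepest encoder width. Each level is two 3×3 same-padded convolutions
with bias, each followed by ReLU; descent is 2×2/stride-2 max pooling;
ascent is a 2×2/stride-2 transposed convolution that halves the filter
count, concatenation with the same-level encoder map (doubling channels
again), and another double convolution. A 1×1 convolution and a logistic
sigmoid produce the per-pixel vessel probability.

Two structural conventions are deliberate:

* **Same padding, no crop.** The original unpadded U-Net shrinks its output;
  vessel masks here must match the input raster exactly, so all 3×3
  convolutions are same-padded and skip concatenation needs no cropping.
* **No normalisation layers, biases everywhere.** The bias-only, norm-free
  reading is what makes the closed-form audit land exactly on
  31,030,593 / 7,759,521 / 1,940,817 trainable parameters for α = 1/2/4;
  adding batch-norm would change those totals.

Parameter totals quoted "in millions" are *truncated* (floored) at one
decimal — 7,759,521 → 7.7, 1,940,817 → 1.9 — the convention consistent with
all three printed sizes.

Inputs whose height or width is not divisible by `2^depth` (e.g. 300×300,
which divides by 4 but not 16) are symmetrically zero-padded to the next
multiple and the output cropped back. This preserves the same-size contract
without resampling; the alternative (resizing) would distort vessel widths.

Weights are Kaiming fan-in initialised from a recorded seed; biases start at
zero.

## NumPy network engine

The layers, losses and optimizer live in `angioseg.nn` and are implemented
directly over NumPy: im2col + one BLAS matrix product per convolution,
non-overlapping unfold for the 2×2/stride-2 transposed convolution, argmax
routing for max-pool gradients, and manual reverse-mode accumulation through
the U topology. Gradients were verified against central finite differences
on small configurations (relative error ~1e-2 at float32, consistent with
single-precision rounding). AdamW uses decoupled weight decay — the decay
term multiplies the parameter directly by `1 − lr·wd` and never enters the
moment estimates — with the conventional moments (0.9, 0.999) and eps 1e-8,
applied to weights and biases alike.

## Training protocol

Batch size 4, learning rate 0.01, weight decay 0.01, binary cross-entropy,
a fixed number of epochs, and best-validation-loss model selection (the
parameters from the epoch with minimal validation loss are restored after
training). One gradient step per mini-batch; no drop-last; shuffling is
reseeded per run from the estimator's `random_state`, so identical
seed + config + data reproduce identical histories. No learning-rate
schedule, no early stopping. Validation losses are computed on un-augmented
images. BCE probabilities are clamped at 1e-7 before the logarithm for
numerical totality; the gradient uses the fused sigmoid+BCE form
`(p − y)/n`.

Thresholding uses strict inequality (`prob > 0.5`), so the degenerate
zero-weight network — whose output is exactly 0.5 everywhere — predicts
all-background deterministically.

## Metrics and aggregation

All six scores derive from per-pixel confusion tallies with vessel as the
positive class. Per tally, F1 coincides algebraically with Dice and
`Dice = 2·IoU/(1+IoU)`; both identities are property-tested. Degenerate
conventions: when truth and prediction are both empty the overlap scores are
1 (perfect agreement); when only the relevant denominator vanishes the score
is 0.

Dataset aggregation defaults to `per_image_mean`: each metric is averaged
over images, except F1, which is reported as the harmonic mean of the *mean*
precision and *mean* recall. Mixing aggregation levels this way makes
aggregated Dice and F1 genuinely different quantities — matching how
published per-image benchmark tables can show Dice ≠ F1, which is impossible
for pooled counts. `micro` (pool counts, then score) is available as the
alternative. The exact recipe behind any given published table cannot be
recovered from scores alone; this choice reproduces the qualitative
behaviour and is stated explicitly wherever results are emitted.

## Data pipeline

Splits are 60/10/30 with floor rounding on train and validation and the
remainder to test — the only convention that yields (80, 13, 41) from 134
items and (369, 61, 186) from 616 — drawn from a seeded permutation and
materialised as plain-text id manifests.

Augmentation is ×7 exactly: identity, horizontal and vertical mirrors, the
three right-angle rotations, and the main-diagonal transpose, applied
jointly to image and mask. The set has 7 members including identity because
the dataset growth it must produce (80→560, 369→2583) forces that count; the
specific members are the natural choice from the dihedral group when only
mirrors and rotations are named. Non-square rasters cannot take 90°/270°/
transpose without changing shape, so those slots are filled with
180°-composed mirror variants (duplicates are accepted) to keep the ×7
arithmetic.

Rasters are read via Pillow (PGM in both ASCII and binary dialects, and
grayscale PNG), scaled into [0,1] by the bit-depth maximum; masks binarize
by `value > 0`.

## Synthetic phantoms

The generator is an original design: no generative model of XCA frames is
being imitated, only their practical complications, one axis each —
low-SNR zones (a disk where vessel contrast is locally damped to 45%), a
catheter distractor (a smooth quadratic curve darkened at half vessel
contrast, absent from the mask), non-uniform illumination (a low-frequency
multiplicative field), additive Gaussian noise, and branching geometry
(random-walk centerlines, probabilistic bifurcation, widths tapering along
each branch and shrinking by `width_decay` per generation). Default raster
sizes 300×300 and 512×512 mirror the two public XCA benchmark formats;
vessels are dark on a bright background as in X-ray imaging.

Defaults keep the vessel pixel fraction within 1–15% (rejection-resampled
from the running seed stream, bounded retries), preserving the class
imbalance real masks show. What the phantoms do **not** emulate: X-ray
attenuation physics, anatomically realistic coronary topology, motion blur,
temporal sequences, or pixel-spacing metadata. Passing the learnability
tests therefore shows the pipeline is sound and the architecture can fit
vessel-like structures — not that it reaches any particular accuracy on
clinical angiograms.

## Problem sizes in tests and the acceptance script

The acceptance script's quantities (parameter totals, latent width) are
closed-form and instant. The learnability check trains the α=4 model on 20
easy 64×64 phantoms (12 train ×7 augmentation, 2 validation, 6 test, 30
epochs) — small rasters chosen as the package's CPU-scale benchmark; the
noise-ordering check averages a fixed-threshold baseline over 20 matched
seeds at four noise levels. Full-scale reproduction on the public DCA1/ICA
datasets (150 epochs at 300×300/512×512) uses the same code paths via the
CLI but is not part of the test suite.

## Known limitations

* Uniform pruning across all layers; no per-layer adaptive reduction.
* Single-channel grayscale input and binary output only.
* The NumPy engine is single-threaded except for BLAS; it is meant for
  CPU-scale experiments and correctness, not for GPU-scale training.
* `per_image_mean` F1 is not the F1 of any single confusion matrix — by
  design (see aggregation above); users comparing against pooled-count
  tables should select `micro`.
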