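# angioseg

Lightweight, filter-pruned U-Net models for blood-vessel segmentation in
X-ray coronary angiography (XCA), with the full training/evaluation pipeline
and a synthetic angiogram generator so every stage runs without external
data.

## The problem and the model

Coronary angiograms show contrast-filled arteries as dark, branching,
tapering curves on a brighter, noisy background; segmenting them supports
stenosis assessment. The standard tool is the U-Net: an encoder `E` that
extracts features through four down-sampling blocks (two 3×3 convolutions +
ReLU each, then 2×2/stride-2 max pooling, doubling the filter count per
level) and a decoder `D` that reconstructs the mask through 2×2
up-convolutions, skip-connection concatenation with the same-level encoder
map, and further double convolutions, ending in a 1×1 convolution and a
sigmoid:

    Y = D(E(X)),   E(X) = {F1..F4},   D(E) = {F̂4..F̂1}

This package builds the whole *pruned family* of that architecture: a single
global reduction factor α removes entire convolutional filters from every
layer **before training**. With the vanilla base widths 64/128/256/512:

| α | encoder widths | latent | parameters | reduction |
|---|----------------|--------|------------|-----------|
| 1 | 64/128/256/512 | 1024   | 31,030,593 (31.0 M) | 1× |
| 2 | 32/64/128/256  | 512    |  7,759,521 (7.7 M)  | 4× |
| 4 | 16/32/64/128   | 256    |  1,940,817 (1.9 M)  | 16× |

The α=4 model ("U-Net-16") is 94% smaller than the vanilla network. The
pipeline is: normalize to [0,1] → train (BCE loss, AdamW with decoupled
weight decay 0.01, lr 0.01, batch 4, best-validation-loss checkpointing)
→ threshold the probability map at t=0.5 → score with IoU, Dice, accuracy,
precision, recall and F1 from per-pixel confusion counts.

The network and its optimizer are implemented in NumPy (im2col convolutions
with manual backpropagation), so the package has no deep-learning framework
dependency and runs anywhere NumPy does.

## Worked example

```python
import numpy as np
from angioseg import (easy_spec, generate_pair, split_dataset, augment,
                      UNetVesselSegmenter)

pairs = [generate_pair(easy_spec(seed=100 + i)) for i in range(20)]
split = split_dataset(20, seed=0)                 # 60/10/30 -> (12, 2, 6)
train = augment([pairs[i] for i in split.train])  # x7 -> 84 training pairs

est = UNetVesselSegmenter(alpha=4, epochs=30, random_state=0)
est.fit([p.image for p in train], [p.mask for p in train],
        X_val=[pairs[i].image for i in split.val],
        y_val=[pairs[i].mask for i in split.val])
print(est.n_parameters_)                                   # 1940817
print(round(est.score([pairs[i].image for i in split.test],
                      [pairs[i].mask for i in split.test]), 3))
```

This prints `1940817` — the trainable-parameter total of the α=4 model — and
a held-out mean IoU of `0.996` on the easy (zero-noise, high-contrast)
synthetic benchmark: the quarter-width network recovers the vessel trees of
phantoms it has never seen almost perfectly.

The same run from the shell:

```sh
angioseg audit --alphas 1,2,4          # the architecture table above
angioseg run --alpha 4 --epochs 30 --n-images 20 --size 64 --seed 0 --out runs/demo
```

`run` writes a manifest, per-epoch losses, predicted masks and a CSV metric
row (`Model,alpha,IoU,DICE,ACC,PREC,REC,F1`, five decimals); re-running with
the same seeds reproduces it bit-for-bit.

## Synthetic angiograms

`angioseg.synth` generates phantom angiogram/mask pairs exhibiting the five
practical complications of XCA frames: low signal-to-noise zones, an
interfering catheter-like curve (darkened in the image but excluded from the
ground truth), non-uniform illumination, additive noise, and vessel
junctions/bifurcations. Vessel trees are seeded random walks with
probabilistic branching and width tapering; the vessel pixel fraction is
kept inside a configurable band (default 1–15%) to preserve the class
imbalance the metrics must cope with. Raising `noise_sigma` provably lowers
a fixed-threshold baseline segmenter's IoU, so difficulty is ordered.

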