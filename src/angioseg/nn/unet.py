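"""The runnable encoder-decoder network built from a :class:`ModelConfig`.

Topology per level: two 3x3 convolutions each followed by ReLU, then a
2x2/stride-2 max pool on the descent; on the ascent a 2x2 up-convolution
halving the filter count, concatenation with the same-level encoder map,
and another double 3x3 convolution.  A 1x1 convolution maps to the output
channels, squashed to a probability map by a logistic sigmoid.  No
normalisation layers and biases everywhere, so the trainable-array
enumeration matches the closed-form audit of :mod:`angioseg.family`.

Inputs whose height or width is not divisible by ``2**depth`` are
symmetrically zero-padded up to the next multiple before the forward pass
and the output cropped back, preserving the same-size contract without
resampling.
"""

from __future__ import annotations

import numpy as np

from ..family import ModelConfig, filter_schedule
from .layers import Conv2d, ConvTranspose2d, MaxPool2d, ReLU, Parameter, sigmoid


class _DoubleConv:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU."""

    def __init__(self, c_in, c_out, k, rng, label):
        self.conv1 = Conv2d(c_in, c_out, k, rng, f"{label}.conv1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, k, rng, f"{label}.conv2")
        self.relu2 = ReLU()

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()

    def forward(self, x):
        return self.relu2.forward(self.conv2.forward(self.relu1.forward(self.conv1.forward(x))))

    def backward(self, d):
        return self.conv1.backward(self.relu1.backward(self.conv2.backward(self.relu2.backward(d))))


class UNet:
    """Filter-pruned U-Net over NumPy arrays.

    Parameters
    ----------
    config : ModelConfig
        Architecture descriptor (``alpha`` selects the family member).
    seed : int or None
        Seed of the Kaiming fan-in weight initialisation. ``None`` builds a
        zero-weight network (useful for degenerate-behaviour checks).
    """

    def __init__(self, config: ModelConfig, seed: int | None = 0):
        self.config = config
        rng = np.random.default_rng(seed) if seed is not None else None
        sched = filter_schedule(config)
        k = config.conv_kernel
        self.enc_blocks, self.pools = [], []
        c_prev = config.in_channels
        for i, w in enumerate(sched.encoder_widths, start=1):
            self.enc_blocks.append(_DoubleConv(c_prev, w, k, rng, f"enc{i}"))
            self.pools.append(MaxPool2d())
            c_prev = w
        b = sched.bottleneck_width
        self.bottleneck = _DoubleConv(c_prev, b, k, rng, "bottleneck")
        self.ups, self.dec_blocks = [], []
        c_above = b
        for i in range(config.depth, 0, -1):
            w = sched.encoder_widths[i - 1]
            self.ups.append(ConvTranspose2d(c_above, w, config.up_kernel, rng, f"dec{i}.up"))
            self.dec_blocks.append(_DoubleConv(2 * w, w, k, rng, f"dec{i}"))
            c_above = w
        self.head = Conv2d(c_above, config.out_channels, 1, rng, "head")
        self._pad = None

    # ------------------------------------------------------------------ params
    def parameters(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for blk, _ in zip(self.enc_blocks, self.pools):
            ps += blk.parameters()
        ps += self.bottleneck.parameters()
        for up, blk in zip(self.ups, self.dec_blocks):
            ps += up.parameters() + blk.parameters()
        ps += self.head.parameters()
        return ps

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, arr in zip(self.parameters(), state):
            p.data[...] = arr

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # ----------------------------------------------------------------- padding
    def _pad_to_multiple(self, x: np.ndarray) -> np.ndarray:
        m = 2 ** self.config.depth
        h, w = x.shape[2:]
        ph, pw = (-h) % m, (-w) % m
        self._pad = (h, w, ph // 2, pw // 2)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)))
        return x

    def _crop_back(self, y: np.ndarray) -> np.ndarray:
        h, w, top, left = self._pad
        return y[:, :, top:top + h, left:left + w]

    # ----------------------------------------------------------------- forward
    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """Raw (pre-sigmoid) output, same spatial size as the input.

        ``x`` is a float array shaped (batch, in_channels, H, W).
        """
        x = np.ascontiguousarray(x, dtype=np.float32)
        x = self._pad_to_multiple(x)
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            f = blk.forward(x)
            skips.append(f)
            x = pool.forward(f)
        x = self.bottleneck.forward(x)
        self._concat_channels = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            u = up.forward(x)
            x = blk.forward(np.concatenate([u, skip], axis=1))
            self._concat_channels.append(u.shape[1])
        return self._crop_back(self.head.forward(x))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel vessel probability map in [0, 1]."""
        return sigmoid(self.forward_logits(x))

    # ---------------------------------------------------------------- backward
    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        h, w, top, left = self._pad
        m = 2 ** self.config.depth
        fh, fw = h + ((-h) % m), w + ((-w) % m)
        if (fh, fw) != (h, w):
            full = np.zeros(dlogits.shape[:2] + (fh, fw), np.float32)
            full[:, :, top:top + h, left:left + w] = dlogits
            dlogits = full
        d = self.head.backward(np.ascontiguousarray(dlogits, dtype=np.float32))
        dskips = []  # gradient flowing into each encoder skip, shallowest first
        for up, blk, cu in zip(self.ups[::-1], self.dec_blocks[::-1],
                               self._concat_channels[::-1]):
            d = blk.backward(d)
            dskips.append(d[:, cu:])
            d = up.backward(np.ascontiguousarray(d[:, :cu]))
        d = self.bottleneck.backward(d)
        for pool, blk, dskip in zip(self.pools[::-1], self.enc_blocks[::-1], dskips[::-1]):
            d = pool.backward(d)
            d = blk.backward(d + dskip)
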