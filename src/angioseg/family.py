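"""Pruned U-Net architecture family.

The family is parameterised by a single global reduction factor ``alpha``:
every convolutional stage of the vanilla U-Net keeps ``1/alpha`` of its
filters, pruned *before* training.  ``alpha=1`` is the unpruned (vanilla)
model with encoder widths 64/128/256/512; ``alpha=4`` yields the 16/32/64/128
model whose latent space holds 256 filters.

This module owns the architecture descriptors and a closed-form trainable
parameter audit; the runnable network itself lives in :mod:`angioseg.nn.unet`.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path


class ConfigurationError(ValueError):
    """Raised when an architecture configuration violates its invariants."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture descriptor for one member of the pruned U-Net family.

    Parameters
    ----------
    alpha : int
        Global filter-reduction factor. Must divide ``vanilla_base_width``.
    depth : int
        Number of down-sampling (and matching up-sampling) blocks.
    vanilla_base_width : int
        Filters in the first encoder block of the unpruned model.
    in_channels, out_channels : int
        Image channels in (1, grayscale) and predicted classes out (1, the
        binary vessel map).
    conv_kernel : int
        Spatial size of the block convolutions (3).
    up_kernel : int
        Spatial size of the up-convolutions (2), applied with stride 2.
    pool_size, pool_stride : int
        Max-pooling window and stride (2, 2).
    """

    alpha: int = 1
    depth: int = 4
    vanilla_base_width: int = 64
    in_channels: int = 1
    out_channels: int = 1
    conv_kernel: int = 3
    up_kernel: int = 2
    pool_size: int = 2
    pool_stride: int = 2

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ConfigurationError(f"alpha must be a positive integer, got {self.alpha}")
        if self.depth < 1:
            raise ConfigurationError(f"depth must be >= 1, got {self.depth}")
        if self.vanilla_base_width % self.alpha != 0:
            raise ConfigurationError(
                f"vanilla_base_width={self.vanilla_base_width} is not divisible "
                f"by alpha={self.alpha}"
            )
        for name in ("vanilla_base_width", "in_channels", "out_channels"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be strictly positive")

    @property
    def base_width(self) -> int:
        """Filters in the first encoder block after pruning."""
        return self.vanilla_base_width // self.alpha

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: int(v) for k, v in d.items() if k in known})


@dataclass(frozen=True)
class FilterSchedule:
    """Filters per encoder level plus the latent (bottleneck) width.

    The width doubles at every descent, and the bottleneck doubles once more
    past the deepest encoder level.
    """

    encoder_widths: tuple
    bottleneck_width: int

    def __post_init__(self) -> None:
        w = self.encoder_widths
        if any(w[i + 1] != 2 * w[i] for i in range(len(w) - 1)):
            raise ConfigurationError("encoder widths must double per level")
        if self.bottleneck_width != 2 * w[-1]:
            raise ConfigurationError("bottleneck must be twice the deepest encoder width")


def filter_schedule(config: ModelConfig) -> FilterSchedule:
    """Filter counts for every level of the configured model.

    The first width is ``vanilla_base_width / alpha`` and each deeper level
    doubles it; the bottleneck doubles the deepest encoder width again.
    """
    w0 = config.base_width
    widths = tuple(w0 * 2**i for i in range(config.depth))
    return FilterSchedule(encoder_widths=widths, bottleneck_width=2 * widths[-1])


@dataclass(frozen=True)
class LayerSpec:
    """One trainable convolution of the model: kernel, fan-in and fan-out."""

    label: str
    kind: str  # "conv" | "up" | "head"
    c_in: int
    c_out: int
    kernel: int

    @property
    def n_params(self) -> int:
        # k*k weights per (c_in, c_out) pair plus one bias per output filter
        return self.kernel**2 * self.c_in * self.c_out + self.c_out


def layer_specs(config: ModelConfig) -> list[LayerSpec]:
    """Ordered trainable-layer specification of the encoder-decoder graph.

    Per encoder level: two 3x3 convolutions (ReLU after each; the 2x2/stride-2
    max-pool holds no weights).  The bottleneck is another double convolution.
    Per decoder level: a 2x2 up-convolution that halves the filter count,
    concatenation with the same-level encoder map (doubling channels), then
    two 3x3 convolutions.  A final 1x1 convolution maps to ``out_channels``.
    """
    sched = filter_schedule(config)
    k, ku = config.conv_kernel, config.up_kernel
    specs: list[LayerSpec] = []
    c_prev = config.in_channels
    for i, w in enumerate(sched.encoder_widths, start=1):
        specs.append(LayerSpec(f"enc{i}.conv1", "conv", c_prev, w, k))
        specs.append(LayerSpec(f"enc{i}.conv2", "conv", w, w, k))
        c_prev = w
    b = sched.bottleneck_width
    specs.append(LayerSpec("bottleneck.conv1", "conv", c_prev, b, k))
    specs.append(LayerSpec("bottleneck.conv2", "conv", b, b, k))
    c_above = b
    for i in range(config.depth, 0, -1):
        w = sched.encoder_widths[i - 1]
        specs.append(LayerSpec(f"dec{i}.up", "up", c_above, w, ku))
        specs.append(LayerSpec(f"dec{i}.conv1", "conv", 2 * w, w, k))
        specs.append(LayerSpec(f"dec{i}.conv2", "conv", w, w, k))
        c_above = w
    specs.append(LayerSpec("head", "head", c_above, config.out_channels, 1))
    return specs


def _trunc1(millions: float) -> float:
    """Truncate (floor) a value in millions to one decimal, e.g. 7.75 -> 7.7."""
    return math.floor(millions * 10) / 10


@dataclass
class ParameterAudit:
    """Exact trainable-parameter tally of one family member."""

    per_layer: list = field(default_factory=list)  # (label, count) tuples
    total: int = 0

    @property
    def total_millions_trunc1(self) -> float:
        return _trunc1(self.total / 1e6)

    def to_json(self) -> str:
        return json.dumps(
            {
                "total": self.total,
                "total_millions_trunc1": self.total_millions_trunc1,
                "per_layer": [{"layer": l, "count": c} for l, c in self.per_layer],
            },
            indent=2,
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["layer", "count"])
            for label, count in self.per_layer:
                w.writerow([label, count])
            w.writerow(["total", self.total])


def count_parameters(config: ModelConfig) -> ParameterAudit:
    """Closed-form trainable parameter count of the configured model.

    Every k x k convolution with fan-in ``c_in`` and fan-out ``c_out``
    contributes ``k^2 * c_in * c_out`` weights plus ``c_out`` biases; the
    up-convolutions and the 1x1 head follow the same rule. The total must
    agree with an enumeration of the built network's trainable arrays.
    """
    per_layer = [(s.label, s.n_params) for s in layer_specs(config)]
    return ParameterAudit(per_layer=per_layer, total=sum(c for _, c in per_layer))


def reduction_factor(alpha: int, **kwargs) -> int:
    """Parameter-count reduction of the ``alpha``-pruned model vs. vanilla,
    rounded to the nearest integer (4x for alpha=2, 16x for alpha=4)."""
    base = count_parameters(ModelConfig(alpha=1, **kwargs)).total
    pruned = count_parameters(ModelConfig(alpha=alpha, **kwargs)).total
    return round(base / pruned)
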