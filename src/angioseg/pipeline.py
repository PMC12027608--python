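"""The four-stage segmentation pipeline: normalize, train/predict,
threshold, evaluate.

Stage contracts: preprocessing is a pure [0,1] rescale by the raster's
bit-depth maximum with no filtering or enhancement; the model emits a
per-pixel vessel probability map; a fixed threshold t=0.5 (strict ``>``)
binarizes it with no morphological refinement; the metrics module scores the
binary result against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.losses import bce_loss, BCE_EPS, DimensionError  # re-exported

__all__ = ["TrainConfig", "TrainHistory", "preprocess", "binarize",
           "bce_loss", "train", "predict", "BCE_EPS",
           "ConfigurationError", "DomainError", "TrainingError"]


class ConfigurationError(ValueError):
    pass


class DomainError(ValueError):
    pass


class TrainingError(RuntimeError):
    """Optimization produced a non-finite loss; carries the failing epoch."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


@dataclass
class TrainConfig:
    """Optimization protocol: mini-batches of 4, 150 epochs, learning rate
    0.01, AdamW-style decoupled weight decay 0.01, BCE loss, fixed output
    threshold t=0.5, best-validation-loss model selection."""

    batch_size: int = 4
    epochs: int = 150
    learning_rate: float = 0.01
    weight_decay: float = 0.01
    threshold: float = 0.5
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError(f"threshold must be in (0,1), got {self.threshold}")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch losses and the best-validation checkpoint bookkeeping."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = 0  # 1-based argmin of val_loss

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch - 1]

    def to_csv(self) -> str:
        lines = ["epoch,train_loss,val_loss"]
        for i, (tr, va) in enumerate(zip(self.train_loss, self.val_loss), start=1):
            lines.append(f"{i},{tr:.6f},{va:.6f}")
        return "\n".join(lines) + "\n"


def preprocess(raw_image: np.ndarray) -> np.ndarray:
    """Normalize a raster linearly into [0,1] by its bit-depth maximum.

    Already-normalized input passes through unchanged (idempotent); no
    filtering or vessel enhancement is applied.
    """
    arr = np.asarray(raw_image, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise DomainError("raster contains non-finite values")
    if arr.size and arr.min() < 0:
        raise DomainError("raster contains negative values")
    peak = arr.max() if arr.size else 0.0
    if peak <= 1.0:
        return arr
    if peak <= 255.0:
        return arr / 255.0
    if peak <= 65535.0:
        return arr / 65535.0
    raise DomainError(f"raster maximum {peak} exceeds 16-bit range")


def binarize(prob_map: np.ndarray, t: float = 0.5) -> np.ndarray:
    """Fixed-threshold postprocessing: pixel is vessel iff ``prob > t``.

    Strict inequality, so a constant-0.5 map (the zero-weight model) yields
    the all-background mask.  Idempotent on already-binary maps.
    """
    if not 0.0 < t < 1.0:
        raise ConfigurationError(f"threshold must be in (0,1), got {t}")
    return (np.asarray(prob_map) > t).astype(np.uint8)


def train(train_pairs, val_pairs, alpha: int = 4, cfg: TrainConfig | None = None,
          **model_kwargs):
    """Fit a pruned U-Net on sample pairs; thin wrapper over the estimator.

    Returns the fitted :class:`~angioseg.estimator.UNetVesselSegmenter`
    (holding the best-validation-loss parameters) and its history.
    """
    from .estimator import UNetVesselSegmenter

    cfg = cfg or TrainConfig()
    est = UNetVesselSegmenter(alpha=alpha, epochs=cfg.epochs,
                              batch_size=cfg.batch_size,
                              learning_rate=cfg.learning_rate,
                              weight_decay=cfg.weight_decay,
                              threshold=cfg.threshold,
                              random_state=cfg.seed, **model_kwargs)
    X = [p.image for p in train_pairs]
    y = [p.mask for p in train_pairs]
    Xv = [p.image for p in val_pairs]
    yv = [p.mask for p in val_pairs]
    est.fit(X, y, X_val=Xv, y_val=yv)
    return est, est.history_


def predict(model, image: np.ndarray) -> np.ndarray:
    """Probability map of a single preprocessed image through a fitted model
    (estimator or raw network)."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 1:
        raise DomainError("predict expects a preprocessed image in [0,1]")
    net = getattr(model, "net_", model)
    return net.forward(arr[None, None].astype(np.float32))[0, 0]
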