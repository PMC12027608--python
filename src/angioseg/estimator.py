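"""Scikit-learn style estimator for pruned U-Net vessel segmentation.

``UNetVesselSegmenter`` wraps architecture construction, AdamW/BCE
optimization with best-validation-loss checkpointing, probability-map
inference and fixed-threshold binarization behind the familiar
``fit`` / ``predict`` / ``score`` surface, so the model composes with
sklearn pipelines and model selection.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .family import ModelConfig
from .metrics import aggregate, confusion
from .nn import UNet, AdamW, bce_loss, bce_grad_logits
from .pipeline import (TrainConfig, TrainHistory, binarize,
                       ConfigurationError, DomainError, TrainingError)


def _as_image_list(X) -> list[np.ndarray]:
    if isinstance(X, np.ndarray) and X.ndim == 3:
        return [X[i] for i in range(X.shape[0])]
    return [np.asarray(x) for x in X]


class UNetVesselSegmenter(BaseEstimator):
    """Filter-pruned U-Net segmenter with the standard training protocol.

    Parameters
    ----------
    alpha : int, default=4
        Global filter-reduction factor; 1 is the vanilla U-Net (31.0 M
        parameters), 2 keeps half the filters per stage (7.7 M), 4 a
        quarter (1.9 M).
    depth : int, default=4
        Number of down/up-sampling levels.
    vanilla_base_width : int, default=64
        First-stage filter count of the unpruned model; must be divisible
        by ``alpha``.
    epochs, batch_size, learning_rate, weight_decay : training protocol
        (defaults 150 / 4 / 0.01 / 0.01, decoupled AdamW weight decay).
    threshold : float, default=0.5
        Fixed probability cut for ``predict`` (strict ``>``).
    random_state : int, default=0
        Seeds weight initialisation and the per-epoch shuffling stream.
    verbose : int, default=0
        Print per-epoch losses when positive.

    Attributes
    ----------
    net_ : UNet
        The fitted network, holding the best-validation-loss parameters.
    history_ : TrainHistory
        Per-epoch train/validation losses and the best epoch (1-based).
    n_parameters_ : int
        Trainable-parameter total of the built network.
    config_ : ModelConfig
        The architecture descriptor actually built.
    """

    def __init__(self, alpha: int = 4, depth: int = 4, vanilla_base_width: int = 64,
                 epochs: int = 150, batch_size: int = 4, learning_rate: float = 0.01,
                 weight_decay: float = 0.01, threshold: float = 0.5,
                 random_state: int = 0, verbose: int = 0):
        self.alpha = alpha
        self.depth = depth
        self.vanilla_base_width = vanilla_base_width
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.threshold = threshold
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ helpers
    def _validate_pairs(self, X, y):
        imgs = _as_image_list(X)
        masks = _as_image_list(y)
        if len(imgs) == 0:
            raise ConfigurationError("empty training set")
        if len(imgs) != len(masks):
            raise ConfigurationError(f"{len(imgs)} images vs {len(masks)} masks")
        shape = imgs[0].shape
        for im, mk in zip(imgs, masks):
            if im.shape != shape or mk.shape != shape:
                raise ConfigurationError("all images and masks must share one shape")
            if im.min() < 0 or im.max() > 1:
                raise DomainError("images must be preprocessed into [0,1]")
            if not np.isin(mk, (0, 1)).all():
                raise DomainError("masks must be binary")
        xb = np.stack(imgs)[:, None].astype(np.float32)
        yb = np.stack(masks)[:, None].astype(np.float32)
        return xb, yb

    def _epoch_loss(self, net, xb, yb) -> float:
        """Weighted mean BCE over the set, forward passes only."""
        total, n = 0.0, xb.shape[0]
        for i in range(0, n, self.batch_size):
            sl = slice(i, i + self.batch_size)
            total += bce_loss(net.forward(xb[sl]), yb[sl]) * (min(i + self.batch_size, n) - i)
        return total / n

    # ---------------------------------------------------------------------- fit
    def fit(self, X, y, X_val=None, y_val=None):
        """Optimize BCE with AdamW; keep the best-validation-loss parameters.

        ``X``/``y`` are the (already augmented, already normalized) training
        images and binary masks; validation data default to the training set
        when not given, which suits smoke runs but not model selection.
        """
        cfg = TrainConfig(batch_size=self.batch_size, epochs=self.epochs,
                          learning_rate=self.learning_rate,
                          weight_decay=self.weight_decay, threshold=self.threshold,
                          seed=self.random_state)
        xb, yb = self._validate_pairs(X, y)
        if X_val is None:
            xv, yv = xb, yb
        else:
            xv, yv = self._validate_pairs(X_val, y_val)

        self.config_ = ModelConfig(alpha=self.alpha, depth=self.depth,
                                   vanilla_base_width=self.vanilla_base_width)
        net = UNet(self.config_, seed=self.random_state)
        self.n_parameters_ = net.n_parameters
        opt = AdamW(net.parameters(), lr=cfg.learning_rate,
                    weight_decay=cfg.weight_decay)
        shuffle_rng = np.random.default_rng([cfg.seed, 1])

        history = TrainHistory()
        best_state, best_val = None, np.inf
        n = xb.shape[0]
        for epoch in range(1, cfg.epochs + 1):
            perm = shuffle_rng.permutation(n)
            running, seen = 0.0, 0
            for i in range(0, n, cfg.batch_size):
                idx = perm[i:i + cfg.batch_size]
                prob = net.forward(xb[idx])
                loss = bce_loss(prob, yb[idx])
                if not np.isfinite(loss):
                    raise TrainingError(f"non-finite training loss at epoch {epoch}",
                                        epoch=epoch)
                net.zero_grad()
                net.backward(bce_grad_logits(prob, yb[idx]))
                opt.step()
                running += loss * len(idx)
                seen += len(idx)
            val = self._epoch_loss(net, xv, yv)
            if not np.isfinite(val):
                raise TrainingError(f"non-finite validation loss at epoch {epoch}",
                                    epoch=epoch)
            history.train_loss.append(running / seen)
            history.val_loss.append(val)
            if val < best_val:
                best_val, best_state = val, net.state()
                history.best_epoch = epoch
            if self.verbose:
                print(f"epoch {epoch:4d}  train {running / seen:.4f}  val {val:.4f}")
        net.load_state(best_state)
        self.net_ = net
        self.history_ = history
        self.best_epoch_ = history.best_epoch
        return self

    # ---------------------------------------------------------------- inference
    def predict_proba(self, X) -> list[np.ndarray]:
        """Per-pixel vessel probability map for each image."""
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        out = []
        for im in _as_image_list(X):
            arr = np.asarray(im, dtype=np.float64)
            if arr.min() < 0 or arr.max() > 1:
                raise DomainError("predict expects preprocessed images in [0,1]")
            out.append(self.net_.forward(arr[None, None].astype(np.float32))[0, 0])
        return out

    def predict(self, X) -> list[np.ndarray]:
        """Binary vessel masks at the fixed threshold."""
        return [binarize(p, self.threshold) for p in self.predict_proba(X)]

    def score(self, X, y) -> float:
        """Mean per-image IoU against ground-truth masks."""
        preds = self.predict(X)
        counts = [confusion(p, np.asarray(t)) for p, t in zip(preds, _as_image_list(y))]
        return aggregate(counts, mode="per_image_mean").iou

    # -------------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: architecture config + parameter arrays."""
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        cfg = self.config_.to_dict()
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.net_.parameters())}
        np.savez(path, __config__=np.array([list(cfg.keys()),
                                            [str(v) for v in cfg.values()]]),
                 __threshold__=np.array([self.threshold]), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "UNetVesselSegmenter":
        with np.load(path, allow_pickle=False) as npz:
            keys, vals = npz["__config__"]
            cfg = ModelConfig.from_dict(dict(zip(keys, vals)))
            est = cls(alpha=cfg.alpha, depth=cfg.depth,
                      vanilla_base_width=cfg.vanilla_base_width,
                      threshold=float(npz["__threshold__"][0]))
            est.config_ = cfg
            net = UNet(cfg, seed=None)
            net.load_state([npz[f"param_{i}"] for i in range(len(net.parameters()))])
            est.net_ = net
            est.n_parameters_ = net.n_parameters
        return est
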