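"""Binary cross-entropy over probability maps."""

from __future__ import annotations

import numpy as np

BCE_EPS = 1e-7  # clamp so log never sees 0 or 1 exactly


class DimensionError(ValueError):
    """Probability map and target mask shapes disagree."""


def bce_loss(prob_map: np.ndarray, truth_mask: np.ndarray, eps: float = BCE_EPS) -> float:
    """Mean per-pixel binary cross-entropy.

    ``-mean(y*log(p) + (1-y)*log(1-p))`` with probabilities clamped to
    ``[eps, 1-eps]`` for numerical totality.
    """
    prob_map = np.asarray(prob_map, dtype=np.float64)
    truth_mask = np.asarray(truth_mask, dtype=np.float64)
    if prob_map.shape != truth_mask.shape:
        raise DimensionError(
            f"probability map {prob_map.shape} vs truth mask {truth_mask.shape}")
    p = np.clip(prob_map, eps, 1.0 - eps)
    y = truth_mask
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def bce_grad_logits(prob_map: np.ndarray, truth_mask: np.ndarray) -> np.ndarray:
    """Gradient of the mean BCE with respect to the pre-sigmoid logits.

    Fusing sigmoid and BCE gives the exact, stable form ``(p - y) / n``.
    """
    n = prob_map.size
    return ((prob_map - truth_mask) / n).astype(np.float32)
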