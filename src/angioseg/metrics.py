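"""Pixel-wise segmentation metrics for binary vessel masks.

All six scores — IoU, Dice, accuracy, precision, recall and F1 — derive from
the per-pixel confusion tallies with the vessel as the positive class.
Probability maps must be thresholded to binary masks before scoring (see
:func:`angioseg.pipeline.binarize`).

Degenerate-count conventions: when both truth and prediction are empty
(only true negatives), the overlap metrics are perfect agreement (1); when
only the relevant denominator vanishes otherwise, the metric is 0.  These
conventions keep every score bounded and monotone on sparse fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


class DomainError(ValueError):
    """Input outside the metric's domain (non-binary mask, empty counts...)."""


class DimensionError(ValueError):
    """Prediction and truth rasters have different shapes."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies: true/false positives and negatives (vessel = positive)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DomainError("confusion counts must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricReport:
    """The six scores, each in [0, 1], over ``n_images`` rasters."""

    iou: float
    dice: float
    acc: float
    prec: float
    rec: float
    f1: float
    n_images: int = 1

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k)
                           for k in ("iou", "dice", "acc", "prec", "rec", "f1", "n_images")})

    def to_csv_row(self, model: str, alpha) -> str:
        """One table row (Model, alpha, IoU, DICE, ACC, PREC, REC, F1), 5 decimals."""
        vals = [self.iou, self.dice, self.acc, self.prec, self.rec, self.f1]
        return ",".join([model, str(alpha)] + [f"{v:.5f}" for v in vals])

    @staticmethod
    def csv_header() -> str:
        return "Model,alpha,IoU,DICE,ACC,PREC,REC,F1"


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise DomainError(f"{name} must contain only 0/1 values")
    return arr.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/TN/FP/FN between a predicted and a ground-truth binary mask."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise DimensionError(f"pred {pred.shape} vs truth {truth.shape}")
    p = _check_binary(pred, "pred")
    t = _check_binary(truth, "truth")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def metric_report(c: ConfusionCounts, n_images: int = 1) -> MetricReport:
    """The six scores of a single confusion tally.

    IoU = tp/(tp+fp+fn); Dice = 2tp/(2tp+fp+fn); accuracy = (tp+tn)/total;
    precision = tp/(tp+fp); recall = tp/(tp+fn); F1 the harmonic mean of
    precision and recall (which, per counts, coincides with Dice).
    """
    if c.n_pixels == 0:
        raise DomainError("cannot score an all-zero confusion tally")
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        # truth and prediction both empty: perfect agreement
        return MetricReport(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, n_images)
    iou = _ratio(c.tp, c.tp + c.fp + c.fn)
    dice = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    acc = _ratio(c.tp + c.tn, c.n_pixels)
    prec = _ratio(c.tp, c.tp + c.fp)
    rec = _ratio(c.tp, c.tp + c.fn)
    f1 = _ratio(2 * prec * rec, prec + rec)
    return MetricReport(iou, dice, acc, prec, rec, f1, n_images)


def aggregate(per_image: Sequence[ConfusionCounts] | Iterable[ConfusionCounts],
              mode: str = "per_image_mean") -> MetricReport:
    """Dataset-level score over per-image confusion tallies.

    ``per_image_mean`` averages each per-image metric arithmetically and
    reports F1 as the harmonic mean of the mean precision and mean recall —
    this mixes aggregation levels on purpose, so aggregated Dice and F1 can
    differ, as they do in per-image-averaged benchmark tables.  ``micro``
    pools the counts first and scores the sum.
    """
    counts = list(per_image)
    if not counts:
        raise DomainError("cannot aggregate an empty list of counts")
    if mode == "micro":
        total = counts[0]
        for c in counts[1:]:
            total = total + c
        return metric_report(total, n_images=len(counts))
    if mode != "per_image_mean":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    reports = [metric_report(c) for c in counts]
    mean = lambda key: float(np.mean([getattr(r, key) for r in reports]))
    prec, rec = mean("prec"), mean("rec")
    f1 = _ratio(2 * prec * rec, prec + rec)
    return MetricReport(mean("iou"), mean("dice"), mean("acc"), prec, rec, f1,
                        n_images=len(counts))
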