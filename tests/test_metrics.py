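"""Six-metric evaluation: confusion tallies, identities, oracles, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angioseg.metrics import (ConfusionCounts, DimensionError, DomainError,
                              aggregate, confusion, metric_report)


def _masks_10x10():
    """6 overlapping, 2 pred-only, 2 truth-only vessel pixels on 10x10."""
    truth = np.zeros((10, 10), dtype=np.uint8)
    pred = np.zeros((10, 10), dtype=np.uint8)
    overlap = [(0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (5, 5)]
    for r, c in overlap:
        truth[r, c] = pred[r, c] = 1
    truth[9, 0] = truth[9, 1] = 1   # missed by pred
    pred[0, 9] = pred[1, 9] = 1     # spurious
    return pred, truth


def test_confusion_identity_and_total_miss():
    ones = np.ones((2, 2), dtype=int)
    zeros = np.zeros((2, 2), dtype=int)
    assert confusion(ones, ones) == ConfusionCounts(4, 0, 0, 0)
    assert confusion(zeros, ones) == ConfusionCounts(0, 0, 0, 4)


def test_confusion_counts_constructed_masks():
    pred, truth = _masks_10x10()
    c = confusion(pred, truth)
    # brute-force per-pixel comparison
    tp = sum(int(pred[r, c_] and truth[r, c_]) for r in range(10) for c_ in range(10))
    assert (c.tp, c.tn, c.fp, c.fn) == (6, 90, 2, 2)
    assert c.tp == tp and c.n_pixels == 100


def test_confusion_input_validation():
    with pytest.raises(DimensionError):
        confusion(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(DomainError):
        confusion(np.full((2, 2), 0.5), np.zeros((2, 2)))


def test_metric_report_on_derived_counts():
    rep = metric_report(ConfusionCounts(6, 90, 2, 2))
    assert rep.iou == pytest.approx(0.6)
    assert rep.dice == pytest.approx(0.75)
    assert rep.acc == pytest.approx(0.96)
    assert rep.prec == pytest.approx(0.75)
    assert rep.rec == pytest.approx(0.75)
    assert rep.f1 == pytest.approx(0.75)


def test_perfect_and_empty_intersection_extremes():
    perfect = metric_report(ConfusionCounts(7, 93, 0, 0))
    assert all(getattr(perfect, k) == 1.0 for k in ("iou", "dice", "acc", "prec", "rec", "f1"))
    miss = metric_report(ConfusionCounts(0, 90, 4, 6))
    assert miss.iou == 0.0 and miss.dice == 0.0


def test_degenerate_conventions():
    # both truth and prediction empty: perfect agreement
    empty = metric_report(ConfusionCounts(0, 100, 0, 0))
    assert empty.iou == empty.dice == empty.prec == empty.rec == empty.f1 == 1.0
    with pytest.raises(DomainError):
        metric_report(ConfusionCounts(0, 0, 0, 0))


counts_st = st.tuples(st.integers(0, 10_000), st.integers(0, 10_000),
                      st.integers(0, 10_000), st.integers(0, 10_000)).filter(
    lambda t: sum(t) > 0)


@settings(max_examples=300, derandomize=True)
@given(counts_st)
def test_algebraic_identities(t):
    """Dice = 2 IoU/(1+IoU) and per-counts F1 = Dice, for any tally."""
    rep = metric_report(ConfusionCounts(*t))
    assert rep.dice == pytest.approx(2 * rep.iou / (1 + rep.iou))
    assert rep.f1 == pytest.approx(rep.dice)
    assert rep.iou <= rep.dice + 1e-12
    for k in ("iou", "dice", "acc", "prec", "rec", "f1"):
        assert 0.0 <= getattr(rep, k) <= 1.0


@settings(max_examples=100, derandomize=True)
@given(counts_st, st.integers(1, 10_000))
def test_tn_inflation_only_moves_accuracy(t, extra):
    base = metric_report(ConfusionCounts(*t))
    inflated = metric_report(ConfusionCounts(t[0], t[1] + extra, t[2], t[3]))
    assert inflated.acc >= base.acc - 1e-12
    for k in ("iou", "dice", "prec", "rec", "f1"):
        assert getattr(inflated, k) == pytest.approx(getattr(base, k))


def _set_oracle(pred, truth):
    """Independent oracle: explicit coordinate-set operations."""
    P = {tuple(ix) for ix in np.argwhere(pred == 1)}
    T = {tuple(ix) for ix in np.argwhere(truth == 1)}
    inter, union = len(P & T), len(P | T)
    n = pred.size
    if not P and not T:
        return dict(iou=1, dice=1, acc=1, prec=1, rec=1)
    return dict(
        iou=inter / union if union else 0.0,
        dice=2 * inter / (len(P) + len(T)) if (P or T) else 0.0,
        acc=(n - len(P ^ T)) / n,
        prec=inter / len(P) if P else 0.0,
        rec=inter / len(T) if T else 0.0,
    )


def test_report_agrees_with_set_operations_oracle(rng):
    for _ in range(30):
        pred = (rng.random((16, 16)) < 0.3).astype(int)
        truth = (rng.random((16, 16)) < 0.3).astype(int)
        rep = metric_report(confusion(pred, truth))
        for key, val in _set_oracle(pred, truth).items():
            assert getattr(rep, key) == pytest.approx(val), key


def test_aggregate_single_and_replicated_images():
    c = ConfusionCounts(6, 90, 2, 2)
    single = metric_report(c)
    for mode in ("per_image_mean", "micro"):
        agg = aggregate([c], mode=mode)
        assert agg.iou == pytest.approx(single.iou)
        agg2 = aggregate([c, c], mode=mode)
        assert agg2.iou == pytest.approx(single.iou)
        assert agg2.n_images == 2


def test_micro_aggregation_pools_counts():
    counts = [ConfusionCounts(6, 90, 2, 2), ConfusionCounts(4, 92, 2, 2)]
    agg = aggregate(counts, mode="micro")
    assert agg.iou == pytest.approx(10 / 18)
    # cross-check against per-pixel brute force on the stacked masks
    pred, truth = _masks_10x10()
    stacked = confusion(np.concatenate([pred, pred]), np.concatenate([truth, truth]))
    assert aggregate([confusion(pred, truth)] * 2, "micro").iou == pytest.approx(
        metric_report(stacked).iou)


def test_mean_aggregation_can_separate_dice_from_f1():
    # mixing aggregation levels (mean Dice vs harmonic mean of mean P/R)
    # makes aggregated Dice and F1 distinct quantities
    counts = [ConfusionCounts(10, 80, 0, 10), ConfusionCounts(10, 80, 10, 0)]
    agg = aggregate(counts, mode="per_image_mean")
    assert agg.f1 != pytest.approx(agg.dice)


def test_aggregate_rejects_empty_and_unknown_mode():
    with pytest.raises(DomainError):
        aggregate([])
    with pytest.raises(ValueError):
        aggregate([ConfusionCounts(1, 1, 1, 1)], mode="macro")


def test_csv_row_is_table_shaped():
    rep = metric_report(ConfusionCounts(6, 90, 2, 2))
    row = rep.to_csv_row("U-Net-16", 4)
    assert row.startswith("U-Net-16,4,")
    assert row.split(",")[2] == "0.60000"
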