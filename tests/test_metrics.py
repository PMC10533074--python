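"""Metric formulas, identities and independent-oracle cross-checks."""

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix

from gaunet.metrics import (
    ConfusionCounts,
    accuracy,
    auc_pixelwise,
    confusion_counts,
    dice_coefficient,
    dice_loss,
    evaluate_batch,
    evaluate_image,
    iou,
    precision,
    recall,
)
from gaunet.errors import ShapeError


def _mw_auc(probs, labels):
    """Independent Mann-Whitney AUC: concordant-pair fraction, ties half."""
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_toy_fixture_counts_and_metrics(toy_masks):
    pred, truth = toy_masks
    c = confusion_counts(pred, truth)
    assert (c.tp, c.fp, c.fn, c.tn) == (3, 1, 1, 11)
    assert c.total == 16
    assert accuracy(c) == 0.875
    assert precision(c) == 0.75
    assert recall(c) == 0.75
    assert dice_coefficient(pred, truth) == 0.75
    assert iou(pred, truth) == 0.6


def test_perfect_and_inverted_predictions():
    truth = np.zeros((4, 4), dtype=int)
    truth[:2, :3] = 1
    truth[2, 0] = 1  # 7 foreground of 16
    c = confusion_counts(truth, truth)
    assert (c.tp, c.tn, c.fp, c.fn) == (7, 9, 0, 0)
    assert accuracy(c) == precision(c) == recall(c) == 1.0
    c_inv = confusion_counts(1 - truth, truth)
    assert c_inv.tp == 0 and c_inv.tn == 0


def test_confusion_matches_sklearn_on_random_masks(rng):
    for _ in range(20):
        pred = rng.random((8, 8)) > 0.5
        truth = rng.random((8, 8)) > 0.5
        c = confusion_counts(pred, truth)
        tn, fp, fn, tp = confusion_matrix(
            truth.ravel().astype(int), pred.ravel().astype(int), labels=[0, 1]
        ).ravel()
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        # set-formula vs count-formula equivalence
        assert dice_coefficient(pred, truth) == pytest.approx(
            2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
        )
        assert iou(pred, truth) == pytest.approx(
            tp / (tp + fp + fn) if (tp + fp + fn) else 1.0
        )


def test_degenerate_denominators_flagged_zero():
    c = ConfusionCounts(tp=0, fp=0, tn=10, fn=2)
    with pytest.warns(RuntimeWarning, match="precision"):
        assert precision(c) == 0.0


def test_shape_mismatch_raises():
    with pytest.raises(ShapeError):
        confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(ShapeError):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


def test_dice_iou_conventions():
    empty = np.zeros((4, 4), dtype=int)
    ones = np.ones((4, 4), dtype=int)
    a = np.eye(4, dtype=int)
    assert dice_coefficient(empty, empty) == 1.0
    assert iou(empty, empty) == 1.0
    assert dice_coefficient(ones, ones) == iou(ones, ones) == 1.0
    assert dice_coefficient(a, 1 - a) == iou(a, 1 - a) == 0.0


def test_dice_loss_examples():
    x = np.zeros(8)
    x[:2] = 1.0
    y = np.zeros(8)
    y[1:3] = 1.0  # |X|=2, |Y|=2, overlap 1
    assert dice_loss(x, y, smooth=0.0) == pytest.approx(0.5)
    assert dice_loss(x, x, smooth=0.0) == pytest.approx(0.0)
    assert dice_loss(x, np.roll(x, 4), smooth=0.0) == pytest.approx(1.0)
    # smoothing keeps the all-empty case defined
    assert dice_loss(np.zeros(8), np.zeros(8), smooth=1.0) == 0.0


def test_dice_identities_on_random_masks(rng):
    for _ in range(30):
        x = (rng.random((6, 6)) > 0.4).astype(float)
        y = (rng.random((6, 6)) > 0.6).astype(float)
        dsc, j = dice_coefficient(x, y), iou(x, y)
        assert dice_loss(x, y, smooth=0.0) + dsc == pytest.approx(1.0)
        assert dsc == pytest.approx(2 * j / (1 + j))
        assert j <= dsc + 1e-12
        # invariance to a simultaneous spatial permutation
        perm = rng.permutation(36)
        assert dice_coefficient(x.ravel()[perm], y.ravel()[perm]) == pytest.approx(dsc)


def test_auc_exact_small_case():
    truth = np.array([1, 1, 0, 0])
    probs = np.array([0.9, 0.4, 0.6, 0.1])
    assert auc_pixelwise(probs, truth) == pytest.approx(0.75)
    assert _mw_auc(probs, truth) == pytest.approx(0.75)


def test_auc_perfect_chance_and_degenerate(rng):
    truth = (rng.random(50) > 0.5).astype(int)
    assert auc_pixelwise(truth.astype(float), truth) == 1.0
    assert auc_pixelwise(np.full(50, 0.3), truth) == pytest.approx(0.5)
    with pytest.warns(RuntimeWarning, match="single-class"):
        assert auc_pixelwise(rng.random(10), np.zeros(10, dtype=int)) == 0.5


def test_auc_matches_pair_count_oracle(rng):
    for _ in range(10):
        probs = rng.random(40)
        truth = (rng.random(40) > 0.3).astype(int)
        if truth.min() == truth.max():
            continue
        assert auc_pixelwise(probs, truth) == pytest.approx(_mw_auc(probs, truth))


def test_evaluate_batch_report(toy_masks):
    pred, truth = toy_masks
    df = evaluate_batch([pred.astype(float), truth.astype(float)], [truth, truth])
    assert list(df["image"]) == ["img_000", "img_001", "mean"]
    assert df.iloc[1]["dsc"] == 1.0
    assert df.iloc[-1]["acc"] == pytest.approx((0.875 + 1.0) / 2)


def test_evaluate_image_all_metrics_in_unit_interval(rng):
    m = evaluate_image(rng.random((8, 8)), (rng.random((8, 8)) > 0.5).astype(int))
    for v in (m.acc, m.pre, m.rec, m.dsc, m.iou, m.auc):
        assert 0.0 <= v <= 1.0
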