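"""Dice-loss training loop used both for fitness evaluation and final training."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import DivergenceError
from .layers import DTYPE
from .model import UNet
from .optimizers import make_optimizer

__all__ = ["dice_loss_and_grad", "train_model", "pixel_accuracy"]


def dice_loss_and_grad(prob: np.ndarray, truth: np.ndarray, smooth: float = 1.0):
    """Smoothed soft Dice loss pooled over the batch, and its gradient wrt prob."""
    p = prob.astype(np.float64, copy=False)
    y = truth.astype(np.float64, copy=False)
    inter = float((p * y).sum())
    total = float(p.sum() + y.sum())
    loss = 1.0 - (2.0 * inter + smooth) / (total + smooth)
    denom = total + smooth
    grad = (-2.0 * y / denom + (2.0 * inter + smooth) / denom**2).astype(prob.dtype)
    return loss, grad


def pixel_accuracy(prob: np.ndarray, truth: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of pixels whose thresholded prediction matches the mask."""
    pred = prob >= threshold
    return float((pred == (truth >= 0.5)).mean())


def train_model(
    model: UNet,
    images: np.ndarray,
    masks: np.ndarray,
    *,
    epochs: int,
    optimizer,
    learning_rate: float,
    batch_size: int,
    seed: int = 0,
    smooth: float = 1.0,
) -> pd.DataFrame:
    """Train in place; returns a per-epoch history (dice_loss, pixel_accuracy).

    ``optimizer`` is a gene code (1-4) or name.  Raises
    :class:`~gaunet.errors.DivergenceError` on a non-finite loss.
    """
    x = model._to_nchw(images)
    y = np.asarray(masks, dtype=DTYPE)
    if y.ndim == 3:
        y = y[:, None]
    opt = make_optimizer(optimizer, learning_rate)
    params = model.parameters()
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, accs = [], []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            prob = model.forward(x[idx], training=True)
            loss, dprob = dice_loss_and_grad(prob, y[idx], smooth)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            model.backward(dprob)
            opt.step(params)
            losses.append(loss)
            accs.append(pixel_accuracy(prob, y[idx]))
        history.append(
            {
                "epoch": epoch,
                "dice_loss": float(np.mean(losses)),
                "pixel_accuracy": float(np.mean(accs)),
            }
        )
    return pd.DataFrame(history)
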