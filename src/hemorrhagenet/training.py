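"""Training loop: Adam with weight decay and clipping, cosine LR decay,
early stopping on validation loss, optional light augmentation.

The L1 sparsity penalty on the clinical gating weights is applied as a
proximal soft-thresholding step after each optimizer update, so that small
gating weights are driven exactly to zero rather than merely shrunk.
"""

from __future__ import annotations

import math

import numpy as np

from .cohort import Cohort
from .config import RunConfig
from .model import HemorrhageNet, joint_loss
from .nn import Adam, clip_by_global_norm

__all__ = ["gradient_step", "train_step", "cosine_lr", "fit", "Trainer"]


def gradient_step(params: list[np.ndarray], grads: list[np.ndarray],
                  lr: float, clip_norm: float = 0.0) -> float:
    """Plain gradient descent update theta <- theta - lr * g, in place.

    Gradients are first rescaled so their global L2 norm is at most
    ``clip_norm`` (0 disables clipping).  Returns the pre-clip norm.
    """
    norm = clip_by_global_norm(grads, clip_norm)
    for p, g in zip(params, grads):
        p -= lr * g
    return norm


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Half-cosine decay from base_lr toward zero across training."""
    if total_epochs <= 1:
        return base_lr
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / (total_epochs - 1)))


def _soft_threshold(w: np.ndarray, amount: float) -> None:
    w[...] = np.sign(w) * np.maximum(np.abs(w) - amount, 0.0)


def _augment(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal flip + brightness jitter + 1-px shift (train only)."""
    out = images.copy()
    n = out.shape[0]
    flip = rng.random(n) < 0.5
    out[flip] = out[flip, :, ::-1]
    out += rng.normal(0.0, 0.02, size=(n, 1, 1, 1))
    shifts = rng.integers(-1, 2, size=(n, 2))
    for i, (dy, dx) in enumerate(shifts):
        out[i] = np.roll(out[i], (dy, dx), axis=(0, 1))
    return np.clip(out, 0.0, 1.0)


def train_step(model: HemorrhageNet, batch: tuple, optimizer: Adam,
               lr: float | None = None, lambda_l1: float = 0.0,
               lambda_entropy: float = 0.0) -> float:
    """One gradient update on a (images, clinical, y, p) batch.

    Returns the batch loss; raises on a non-finite loss.  The model's
    iteration counter is always incremented, even at lr=0.
    """
    images, clinical, y, p = batch
    if len(y) == 0:
        raise ValueError("empty batch")
    model.zero_grad()
    cache = model.forward(images, clinical, train=True)
    loss = model.loss_and_backward(cache, y, p, lambda_entropy=lambda_entropy,
                                   lambda_l1=lambda_l1)
    eff_lr = optimizer.lr if lr is None else lr
    optimizer.step(model.parameters(), model.gradients(), lr=eff_lr)
    if lambda_l1 > 0.0 and eff_lr > 0.0:
        _soft_threshold(model.gating_weights, eff_lr * lambda_l1)
    model.iteration += 1
    return loss


def _split_arrays(cohort: Cohort, name: str):
    return cohort.split(name).arrays()


def evaluate_loss(model: HemorrhageNet, arrays, lam: float,
                  batch_size: int = 256) -> float:
    images, clinical, y, p = arrays
    n = len(y)
    total = 0.0
    for lo in range(0, n, batch_size):
        sl = slice(lo, min(lo + batch_size, n))
        cache = model.forward(images[sl], clinical[sl])
        total += joint_loss(cache["class_probs"], y[sl], cache["prognosis"],
                            p[sl], lam, reduction="sum")
    return total / n


def fit(cohort: Cohort, config: RunConfig,
        model: HemorrhageNet | None = None) -> tuple[HemorrhageNet, list[dict]]:
    """Train on the cohort's train split, early-stopping on the val split.

    Returns the model restored to its best-validation parameters and a
    per-epoch log (train loss, val loss, learning rate).
    """
    train_arr = _split_arrays(cohort, "train")
    val_arr = _split_arrays(cohort, "val")
    if len(train_arr[2]) == 0:
        raise ValueError("train split is empty")
    if len(val_arr[2]) == 0:
        raise ValueError("val split is empty")

    if model is None:
        model = HemorrhageNet(config, d_clin=len(cohort.schema))
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(lr=config.learning_rate, beta1=config.beta1,
                     beta2=config.beta2, weight_decay=config.weight_decay,
                     clip_norm=config.clip_norm)

    images, clinical, y, p = train_arr
    n = len(y)
    best_val = math.inf
    best_state = model.state_copy()
    stall = 0
    log: list[dict] = []
    for epoch in range(config.epochs):
        lr = (cosine_lr(config.learning_rate, epoch, config.epochs)
              if config.cosine_schedule else config.learning_rate)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb = images[idx]
            if config.augment:
                xb = _augment(xb, rng)
            epoch_loss += train_step(
                model, (xb, clinical[idx], y[idx], p[idx]), optimizer, lr=lr,
                lambda_l1=config.lambda_l1, lambda_entropy=config.lambda_entropy)
            n_batches += 1
        val_loss = evaluate_loss(model, val_arr, config.lambda_prognosis)
        log.append({"epoch": epoch, "lr": lr,
                    "train_loss": epoch_loss / max(n_batches, 1),
                    "val_loss": val_loss})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.state_copy()
            stall = 0
        else:
            stall += 1
            if stall > config.patience:
                break
    model.load_state(best_state)
    return model, log
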