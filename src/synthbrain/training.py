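"""Losses and training loops.

Segmenters and the denoiser minimize the average soft Dice loss

    L = 1 - (1/K) * sum_k [ 2 * sum(Y_k T_k) / (sum(Y_k^2) + sum(T_k^2)) ]

over the K output labels, where Y_k is the soft prediction and T_k the
one-hot ground truth; the QC regressor minimizes a sum of squares between
predicted and true per-region Dice scores. All modules train separately
with Adam; upstream modules are frozen and audited by parameter checksum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .nn import Adam, params_checksum
from .nets import Network

__all__ = [
    "TrainingConfig",
    "soft_dice_loss",
    "soft_dice_loss_grad",
    "sum_of_squares_loss",
    "train_module",
    "FrozenWeightsError",
]

#: Stabilizer added to the soft-Dice numerator and denominator so labels
#: that are empty in both prediction and target contribute a perfect term.
DICE_EPS = 1e-6


class FrozenWeightsError(RuntimeError):
    """A module that must stay frozen was mutated during training."""


@dataclass
class TrainingConfig:
    """Optimization settings. The defaults are the published full-scale
    regime (Adam, learning rate 1e-5; segmenters ~300k steps, regressor
    ~50k); desk-scale presets override ``steps`` and ``learning_rate``."""

    learning_rate: float = 1e-5
    steps: int = 300_000
    seed: int = 0
    checkpoint_every: int = 0  # 0 = no intermediate checksums
    loss: str = "soft_dice"  # or "sum_of_squares"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.loss not in ("soft_dice", "sum_of_squares"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @classmethod
    def toy(cls, steps: int = 300, learning_rate: float = 1e-3, seed: int = 0,
            loss: str = "soft_dice") -> "TrainingConfig":
        return cls(learning_rate=learning_rate, steps=steps, seed=seed, loss=loss)


def _check_dice_shapes(pred: np.ndarray, target: np.ndarray) -> None:
    if pred.shape != target.shape:
        raise ValueError(f"pred shape {pred.shape} != target shape {target.shape}")
    if pred.ndim < 2:
        raise ValueError("expected a (K, ...) probability tensor")


def soft_dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = DICE_EPS) -> float:
    """Average soft Dice loss over labels; 0 iff pred equals the one-hot
    target exactly, at most 1."""
    _check_dice_shapes(pred, target)
    k = pred.shape[0]
    p = pred.reshape(k, -1).astype(np.float64)
    t = target.reshape(k, -1).astype(np.float64)
    num = 2.0 * (p * t).sum(axis=1) + eps
    den = (p**2).sum(axis=1) + (t**2).sum(axis=1) + eps
    return float(1.0 - (num / den).mean())


def soft_dice_loss_grad(
    pred: np.ndarray, target: np.ndarray, eps: float = DICE_EPS
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the soft prediction."""
    _check_dice_shapes(pred, target)
    k = pred.shape[0]
    shape = pred.shape
    p = pred.reshape(k, -1).astype(np.float64)
    t = target.reshape(k, -1).astype(np.float64)
    inter = (p * t).sum(axis=1)
    num = 2.0 * inter + eps
    den = (p**2).sum(axis=1) + (t**2).sum(axis=1) + eps
    loss = float(1.0 - (num / den).mean())
    # d/dp of -num/den per label, averaged over K
    g = -(2.0 * t * den[:, None] - num[:, None] * 2.0 * p) / den[:, None] ** 2
    return loss, (g / k).reshape(shape).astype(np.float32)


def sum_of_squares_loss(
    pred_scores: np.ndarray, true_scores: np.ndarray
) -> float:
    """Sum of squared differences between predicted and true score vectors."""
    pred_scores = np.asarray(pred_scores, dtype=float)
    true_scores = np.asarray(true_scores, dtype=float)
    if pred_scores.shape != true_scores.shape:
        raise ValueError(
            f"score vectors differ in shape: {pred_scores.shape} vs {true_scores.shape}"
        )
    return float(((pred_scores - true_scores) ** 2).sum())


def train_module(
    net: Network,
    data_source: Callable[[int], tuple[np.ndarray, np.ndarray]],
    cfg: TrainingConfig,
    frozen_upstream: Sequence[Network] | None = None,
) -> tuple[Network, np.ndarray]:
    """Train one module with Adam, one fresh example per step.

    ``data_source(step)`` must return an ``(input, target)`` pair matching
    the network spec: a one-hot target tensor for the soft-Dice loss, a
    score vector for the sum-of-squares loss. Frozen upstream modules are
    checksummed before and after the loop; any mutation raises
    :class:`FrozenWeightsError`. Returns the trained network and the
    per-step loss trace.
    """
    if net.frozen:
        raise FrozenWeightsError("cannot train a frozen module")
    upstream = list(frozen_upstream or [])
    before = [u.checksum() for u in upstream]

    opt = Adam(net.params(), lr=cfg.learning_rate)
    trace = np.empty(cfg.steps, dtype=np.float64)
    for step in range(cfg.steps):
        x, t = data_source(step)
        y = net.forward(x)
        if cfg.loss == "soft_dice":
            loss, gy = soft_dice_loss_grad(y, t)
        else:
            loss = sum_of_squares_loss(y, t)
            gy = (2.0 * (y - t)).astype(np.float32)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss {loss} at step {step}; "
                f"|y|max={np.abs(y).max():.3g} lr={cfg.learning_rate}"
            )
        trace[step] = loss
        opt.zero_grad()
        net.backward(gy)
        opt.step()

    after = [u.checksum() for u in upstream]
    if before != after:
        raise FrozenWeightsError("frozen upstream weights changed during training")
    return net, trace
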