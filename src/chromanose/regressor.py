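"""BP-ANN regression of the adulteration level.

A three-layer feed-forward network (inputs p — hidden h — one output) is
trained by back-propagation: gradient descent with momentum on the mean
squared error. Inputs and targets are min–max normalized to [0, 1]
column-wise before training, and predictions are mapped back through the
inverse of the output normalization (no clamping, so predictions can fall
slightly outside [0, 1]).

Hyperparameters follow the fixed recipe this kind of e-nose calibration
uses: learning rate 0.1, momentum 0.1, tanh hidden activation with a linear
output unit, stopping at training MSE ≤ 0.0002 (normalized scale) or 10 000
epochs, whichever comes first. Weights initialize uniform on (−0.5, 0.5)
from the seed. Training is full-batch by default; an online (per-sample)
mode is available via ``batch_mode="online"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemometrics import NormalizationParams, minmax_apply, minmax_fit, minmax_invert
from .errors import DomainError, TrainingError

__all__ = [
    "BPANNHyperparams",
    "BPANNModel",
    "bpann_train",
    "bpann_predict",
    "bpann_select_hidden",
]


@dataclass
class BPANNHyperparams:
    learning_rate: float = 0.1
    momentum: float = 0.1
    target_error: float = 0.0002  # training MSE on the normalized scale
    max_epochs: int = 10_000
    init_scale: float = 0.5  # weights start uniform on (−init_scale, init_scale)
    batch_mode: str = "full"  # "full" | "online"

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or not 0 <= self.momentum < 1:
            raise DomainError("learning_rate must be ≥ 0 and momentum in [0, 1)")
        if self.target_error <= 0 or self.max_epochs < 1:
            raise DomainError("target_error must be > 0 and max_epochs ≥ 1")
        if self.batch_mode not in ("full", "online"):
            raise DomainError(f"unknown batch_mode {self.batch_mode!r}")


@dataclass
class BPANNModel:
    W1: np.ndarray  # h × p
    b1: np.ndarray  # (h,)
    W2: np.ndarray  # 1 × h
    b2: np.ndarray  # (1,)
    norm_in: NormalizationParams
    norm_out: NormalizationParams
    h: int
    seed: int
    hyper: BPANNHyperparams
    loss_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    final_epoch: int = 0
    final_mse: float = np.nan
    converged: bool = False


def _forward(W1, b1, W2, b2, Xn):
    H = np.tanh(Xn @ W1.T + b1)
    out = H @ W2.T + b2
    return H, out


def _loss_and_grads(W1, b1, W2, b2, Xn, yn):
    """MSE loss and analytic gradients for the tanh-hidden / linear-output net.

    ``yn`` is (n, 1) on the normalized scale. Exposed at module level so the
    gradients can be checked against finite differences.
    """
    n = Xn.shape[0]
    H, out = _forward(W1, b1, W2, b2, Xn)
    err = out - yn  # n × 1
    loss = float(np.mean(err**2))
    dout = 2.0 * err / n
    gW2 = dout.T @ H
    gb2 = dout.sum(axis=0)
    dH = dout @ W2
    dpre = dH * (1.0 - H**2)
    gW1 = dpre.T @ Xn
    gb1 = dpre.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


def bpann_train(
    scores_train: np.ndarray,
    levels_train: np.ndarray,
    h: int,
    seed: int = 0,
    hyper: BPANNHyperparams | None = None,
) -> BPANNModel:
    """Train the p–h–1 network by gradient descent with momentum.

    Deterministic under a fixed seed and data. Raises
    :class:`chromanose.errors.TrainingError` (carrying the failing epoch) if
    the loss becomes non-finite.
    """
    if h < 1:
        raise DomainError(f"hidden-node count must be ≥ 1, got {h}")
    hyper = hyper or BPANNHyperparams()
    X = np.atleast_2d(np.asarray(scores_train, dtype=float))
    y = np.asarray(levels_train, dtype=float).reshape(-1, 1)
    if X.shape[0] != y.shape[0]:
        raise DomainError("scores and levels length mismatch")
    if (y < 0).any() or (y > 1).any():
        raise DomainError("levels must lie in [0, 1]")
    norm_in = minmax_fit(X)
    norm_out = minmax_fit(y)
    Xn = minmax_apply(norm_in, X)
    yn = minmax_apply(norm_out, y)
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    a = hyper.init_scale
    W1 = rng.uniform(-a, a, size=(h, p))
    b1 = rng.uniform(-a, a, size=h)
    W2 = rng.uniform(-a, a, size=(1, h))
    b2 = rng.uniform(-a, a, size=1)
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)
    lr, mom = hyper.learning_rate, hyper.momentum
    losses = []
    converged = False
    epoch = 0
    for epoch in range(1, hyper.max_epochs + 1):
        if hyper.batch_mode == "full":
            loss, (gW1, gb1, gW2, gb2) = _loss_and_grads(W1, b1, W2, b2, Xn, yn)
            if not np.isfinite(loss):
                raise TrainingError(f"training diverged at epoch {epoch}", epoch=epoch)
            losses.append(loss)
            if loss <= hyper.target_error:
                converged = True
                break
            vW1 = mom * vW1 - lr * gW1
            vb1 = mom * vb1 - lr * gb1
            vW2 = mom * vW2 - lr * gW2
            vb2 = mom * vb2 - lr * gb2
            W1 += vW1
            b1 += vb1
            W2 += vW2
            b2 += vb2
        else:  # online: per-sample updates, epoch loss recorded after the pass
            for i in range(Xn.shape[0]):
                _, (gW1, gb1, gW2, gb2) = _loss_and_grads(
                    W1, b1, W2, b2, Xn[i : i + 1], yn[i : i + 1]
                )
                vW1 = mom * vW1 - lr * gW1
                vb1 = mom * vb1 - lr * gb1
                vW2 = mom * vW2 - lr * gW2
                vb2 = mom * vb2 - lr * gb2
                W1 += vW1
                b1 += vb1
                W2 += vW2
                b2 += vb2
            loss, _ = _loss_and_grads(W1, b1, W2, b2, Xn, yn)
            if not np.isfinite(loss):
                raise TrainingError(f"training diverged at epoch {epoch}", epoch=epoch)
            losses.append(loss)
            if loss <= hyper.target_error:
                converged = True
                break
    return BPANNModel(
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        norm_in=norm_in,
        norm_out=norm_out,
        h=h,
        seed=seed,
        hyper=hyper,
        loss_curve=np.asarray(losses),
        final_epoch=epoch,
        final_mse=losses[-1] if losses else np.nan,
        converged=converged,
    )


def bpann_predict(model: BPANNModel, scores: np.ndarray) -> np.ndarray:
    """Forward pass followed by the inverse output normalization.

    Values may fall slightly outside [0, 1]; they are not clamped.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[1] != model.W1.shape[1]:
        raise DomainError(f"expected {model.W1.shape[1]} features, got {X.shape[1]}")
    Xn = minmax_apply(model.norm_in, X)
    _, out = _forward(model.W1, model.b1, model.W2, model.b2, Xn)
    return minmax_invert(model.norm_out, out).ravel()


def bpann_select_hidden(
    scores_train: np.ndarray,
    levels_train: np.ndarray,
    scores_val: np.ndarray,
    levels_val: np.ndarray,
    h_grid: Sequence[int],
    seed: int = 0,
    hyper: BPANNHyperparams | None = None,
) -> tuple[int, list[tuple[int, float]]]:
    """Pick the hidden-node count minimizing validation RMSE (level scale).

    Returns ``(best_h, trace)``; ties resolve to the smallest h.
    """
    grid = sorted(set(int(h) for h in h_grid))
    if not grid:
        raise DomainError("h_grid must be non-empty")
    yv = np.asarray(levels_val, dtype=float).ravel()
    trace: list[tuple[int, float]] = []
    best_h, best_rmse = grid[0], np.inf
    for h in grid:
        model = bpann_train(scores_train, levels_train, h, seed=seed, hyper=hyper)
        pred = bpann_predict(model, scores_val)
        rmse = float(np.sqrt(np.mean((pred - yv) ** 2)))
        trace.append((h, rmse))
        if rmse < best_rmse:
            best_h, best_rmse = h, rmse
    return best_h, trace
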