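"""Fisher LDA and extreme-learning-machine classifiers.

Fisher linear discriminant analysis projects the p-dimensional inputs onto
s ≤ min(k−1, p) discriminant functions (DFs) — the axes maximizing
between-class relative to within-class scatter, obtained from the
generalized eigenproblem S_b v = λ S_w v — and assigns an unknown sample to
the class whose centroid is nearest in DF space (Euclidean distance).

The extreme learning machine is a single-hidden-layer feed-forward network
whose input weights and biases are drawn randomly (uniform on [−1, 1]) and
*never trained*; only the hidden-to-output weights β are fitted, in closed
form, as the minimum-norm least-squares solution β = H⁺ T with
H = S(X Wᵀ + b) the hidden-layer matrix under the sigmoid activation
S(x) = 1/(1 + e^−x) and T the 0/1 one-hot class coding. With L hidden
neurons equal to the number of distinct training samples, H is square and
generically invertible, so the network interpolates its training labels.

Ties in every argmin/argmax resolve to the first class in the fixed class
order (pure_beef < mixture < pure_pork).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.special import expit

from .data import CLASS_ORDER, one_hot
from .errors import DomainError

__all__ = [
    "FisherLDAModel",
    "ELMModel",
    "lda_fit",
    "lda_predict",
    "elm_fit",
    "elm_predict",
    "elm_decision",
    "elm_select_hidden",
]


@dataclass
class FisherLDAModel:
    df_coefficients: np.ndarray  # p × s, columns = discriminant functions
    s: int
    class_centroids: np.ndarray  # k × s, per-class mean in DF space
    df_contribution: np.ndarray  # per-DF eigenvalue share, sums to 1
    class_order: tuple[str, ...]


@dataclass
class ELMModel:
    input_weights: np.ndarray  # L × p
    biases: np.ndarray  # (L,)
    output_weights: np.ndarray  # L × k (β, minimum-norm least squares)
    L: int
    class_order: tuple[str, ...]
    seed: int


def _ordered_classes(labels: Sequence[str], class_order: Sequence[str] | None) -> tuple[str, ...]:
    present = set(labels)
    if class_order is None:
        if present <= set(CLASS_ORDER):
            return tuple(c for c in CLASS_ORDER if c in present)
        return tuple(sorted(present))
    missing = present - set(class_order)
    if missing:
        raise DomainError(f"labels outside class_order: {sorted(missing)}")
    return tuple(class_order)


def lda_fit(
    scores: np.ndarray,
    labels: Sequence[str],
    class_order: Sequence[str] | None = None,
) -> FisherLDAModel:
    """Fit Fisher LDA: s = min(k−1, p) discriminant axes plus class centroids.

    The axes solve the generalized eigenproblem of between- vs within-class
    scatter; a near-singular within-class scatter receives a small ridge
    (1e−6 · trace/p on the diagonal) with a warning. ``df_contribution`` is
    each retained DF's share of the retained eigenvalue mass.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = list(labels)
    if X.shape[0] != len(labels):
        raise DomainError("scores and labels length mismatch")
    classes = _ordered_classes(labels, class_order)
    k, p = len(classes), X.shape[1]
    if k < 2:
        raise DomainError("LDA needs at least 2 classes")
    grand_mean = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    class_means = np.zeros((k, p))
    for j, c in enumerate(classes):
        Xc = X[[lab == c for lab in labels]]
        if Xc.shape[0] < 2:
            raise DomainError(f"class {c!r} has fewer than 2 samples")
        mc = Xc.mean(axis=0)
        class_means[j] = mc
        D = Xc - mc
        Sw += D.T @ D
        dm = (mc - grand_mean)[:, None]
        Sb += Xc.shape[0] * (dm @ dm.T)

    w_evals = np.linalg.eigvalsh(Sw)
    if w_evals[0] <= 1e-10 * max(1.0, np.trace(Sw)):
        warnings.warn(
            "singular within-class scatter: adding ridge 1e-6·trace/p",
            stacklevel=2,
        )
        Sw = Sw + (1e-6 * np.trace(Sw) / p + 1e-12) * np.eye(p)
    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    s = min(k - 1, p)
    W = evecs[:, :s].copy()
    # unit-norm, sign-fixed axes for reproducibility (scale/sign not identifiable)
    for j in range(s):
        nrm = np.linalg.norm(W[:, j])
        if nrm > 0:
            W[:, j] /= nrm
        if W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] = -W[:, j]
    top = evals[:s]
    contrib = top / top.sum() if top.sum() > 0 else np.full(s, 1.0 / s)
    centroids = class_means @ W
    return FisherLDAModel(
        df_coefficients=W,
        s=s,
        class_centroids=centroids,
        df_contribution=contrib,
        class_order=classes,
    )


def lda_predict(model: FisherLDAModel, scores: np.ndarray) -> list[str]:
    """Nearest-centroid assignment in discriminant space.

    Ties go to the first class in ``model.class_order``.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[1] != model.df_coefficients.shape[0]:
        raise DomainError(
            f"expected {model.df_coefficients.shape[0]} features, got {X.shape[1]}"
        )
    Z = X @ model.df_coefficients
    d2 = ((Z[:, None, :] - model.class_centroids[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)  # argmin returns the first minimum → tie rule
    return [model.class_order[i] for i in idx]


def elm_fit(
    scores: np.ndarray,
    targets: np.ndarray,
    L: int,
    seed: int = 0,
    class_order: Sequence[str] = CLASS_ORDER,
) -> ELMModel:
    """Fit an ELM: random U(−1, 1) input weights/biases, closed-form β.

    ``targets`` is the one-hot class matrix (use :func:`chromanose.data.one_hot`).
    β is the minimum-norm least-squares solution pinv(H) @ targets, so the
    training residual H β − T is orthogonal to the column space of H.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    if L < 1:
        raise DomainError(f"hidden-neuron count must be ≥ 1, got {L}")
    if X.shape[0] < 2:
        raise DomainError("elm_fit needs at least 2 samples")
    if X.shape[0] != T.shape[0]:
        raise DomainError("scores and targets row mismatch")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(L, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=L)
    H = expit(X @ W.T + b)
    beta = np.linalg.pinv(H) @ T
    return ELMModel(
        input_weights=W,
        biases=b,
        output_weights=beta,
        L=L,
        class_order=tuple(class_order),
        seed=seed,
    )


def elm_decision(model: ELMModel, scores: np.ndarray) -> np.ndarray:
    """Raw network output S(X Wᵀ + b) β, one column per class."""
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[1] != model.input_weights.shape[1]:
        raise DomainError(
            f"expected {model.input_weights.shape[1]} features, got {X.shape[1]}"
        )
    H = expit(X @ model.input_weights.T + model.biases)
    return H @ model.output_weights


def elm_predict(model: ELMModel, scores: np.ndarray) -> list[str]:
    """Argmax class decoding; ties go to the first class in class_order."""
    Y = elm_decision(model, scores)
    idx = np.argmax(Y, axis=1)
    return [model.class_order[i] for i in idx]


def elm_select_hidden(
    scores_train: np.ndarray,
    labels_train: Sequence[str],
    scores_val: np.ndarray,
    labels_val: Sequence[str],
    L_grid: Sequence[int],
    seed: int = 0,
    class_order: Sequence[str] = CLASS_ORDER,
) -> tuple[int, list[tuple[int, float]]]:
    """Pick the hidden-neuron count minimizing validation RMSE.

    RMSE is computed on the one-hot representation of the network output.
    Returns ``(best_L, trace)`` where trace lists (L, validation RMSE) for
    the whole grid; ties resolve to the smallest L.
    """
    grid = sorted(set(int(L) for L in L_grid))
    if not grid:
        raise DomainError("L_grid must be non-empty")
    T_train = one_hot(labels_train, class_order)
    T_val = one_hot(labels_val, class_order)
    trace: list[tuple[int, float]] = []
    best_L, best_rmse = grid[0], np.inf
    for L in grid:
        model = elm_fit(scores_train, T_train, L, seed=seed, class_order=class_order)
        resid = elm_decision(model, scores_val) - T_val
        rmse = float(np.sqrt(np.mean(resid**2)))
        trace.append((L, rmse))
        if rmse < best_rmse:
            best_L, best_rmse = L, rmse
    return best_L, trace
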