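"""PCA preprocessing and min–max normalization.

Sensor-array features are strongly collinear (every dye responds to many
volatiles and many dyes respond to the same volatile), so principal
component analysis of the covariance matrix is used to replace the 3N raw
features with a handful of uncorrelated scores before any model is fitted.
Components are selected by cumulative contribution rate (eigenvalue share of
the covariance trace); network inputs and targets are subsequently rescaled
to [0, 1] column-wise by the min–max map y = (x − x_min)/(x_max − x_min).

Conventions: the covariance uses the n−1 denominator; eigenvectors are
sign-fixed so their largest-magnitude entry is positive (signs are not
identifiable); PCA is fitted on raw difference profiles, with min–max
normalization applied afterwards to the scores that feed the networks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DomainError

__all__ = [
    "PCAModel",
    "NormalizationParams",
    "pca_fit",
    "pca_transform",
    "select_components",
    "minmax_fit",
    "minmax_apply",
    "minmax_invert",
]


@dataclass
class PCAModel:
    mean_: np.ndarray  # per-feature mean (p,)
    loadings: np.ndarray  # orthonormal eigenvectors, columns = components (p × p)
    eigenvalues: np.ndarray  # descending, ≥ 0
    contribution: np.ndarray  # eigenvalue share of the trace, sums to 1
    k_selected: int  # components retained for transform (default: all)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "mean": self.mean_.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "contribution": self.contribution.tolist(),
            "k_selected": self.k_selected,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            mean_=np.array(doc["mean"]),
            loadings=np.array(doc["loadings"]),
            eigenvalues=np.array(doc["eigenvalues"]),
            contribution=np.array(doc["contribution"]),
            k_selected=int(doc["k_selected"]),
        )


@dataclass
class NormalizationParams:
    """Per-column training minima/maxima of the min–max map."""

    xmin: np.ndarray
    xmax: np.ndarray

    def __post_init__(self) -> None:
        self.xmin = np.atleast_1d(np.asarray(self.xmin, dtype=float))
        self.xmax = np.atleast_1d(np.asarray(self.xmax, dtype=float))
        if self.xmin.shape != self.xmax.shape:
            raise DomainError("xmin and xmax must have matching shapes")
        if (self.xmax < self.xmin).any():
            raise DomainError("xmax must be ≥ xmin per column")


def pca_fit(X: np.ndarray) -> PCAModel:
    """Eigendecomposition of the sample covariance of mean-centered ``X``.

    Deterministic up to per-component sign; the sign is fixed by making the
    largest-magnitude loading entry of each component positive. A constant
    input matrix yields all-zero eigenvalues and (with a warning) uniform
    contributions.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DomainError("pca_fit needs a 2-D matrix with ≥ 2 samples")
    if not np.isfinite(X).all():
        raise DomainError("pca_fit input contains non-finite values")
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.where(np.abs(evals) < 1e-12 * max(1.0, abs(evals[0])), 0.0, evals)
    # sign convention: largest-|entry| of each loading column is positive
    for j in range(p):
        col = evecs[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            evecs[:, j] = -col
    total = evals.sum()
    if total <= 0:
        warnings.warn(
            "constant input matrix: all eigenvalues are zero; "
            "contributions defined as uniform",
            stacklevel=2,
        )
        contribution = np.full(p, 1.0 / p)
        evals = np.zeros(p)
    else:
        contribution = evals / total
    return PCAModel(
        mean_=mean,
        loadings=evecs,
        eigenvalues=evals,
        contribution=contribution,
        k_selected=p,
    )


def pca_transform(model: PCAModel, X: np.ndarray, k: int | None = None) -> np.ndarray:
    """Project (centered) ``X`` onto the first ``k`` principal axes."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = model.loadings.shape[0]
    if X.shape[1] != p:
        raise DomainError(f"expected {p} features, got {X.shape[1]}")
    k = model.k_selected if k is None else int(k)
    if not 1 <= k <= p:
        raise DomainError(f"k must lie in [1, {p}], got {k}")
    return (X - model.mean_) @ model.loadings[:, :k]


def select_components(model: PCAModel, threshold: float) -> int:
    """Smallest k whose cumulative contribution rate reaches ``threshold``.

    Monotone non-decreasing in the threshold; ``threshold = 1.0`` returns the
    number of nonzero eigenvalues. Sets ``model.k_selected``.
    """
    if not 0.0 < threshold <= 1.0:
        raise DomainError(f"threshold must lie in (0, 1], got {threshold}")
    cum = np.cumsum(model.contribution)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, model.contribution.size)
    model.k_selected = k
    return k


def minmax_fit(X: np.ndarray) -> NormalizationParams:
    """Per-column minima and maxima of the training matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise DomainError("minmax_fit needs at least one row")
    params = NormalizationParams(xmin=X.min(axis=0), xmax=X.max(axis=0))
    if (params.xmax == params.xmin).any():
        warnings.warn(
            "constant column(s): min–max normalization maps them to 0",
            stacklevel=2,
        )
    return params


def minmax_apply(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    """y = (x − x_min)/(x_max − x_min), column-wise.

    Training rows land in [0, 1]; values outside the training range
    extrapolate beyond it (no clamping). Constant columns map to 0.
    """
    X = np.asarray(X, dtype=float)
    span = params.xmax - params.xmin
    safe = np.where(span == 0, 1.0, span)
    Y = (X - params.xmin) / safe
    return np.where(span == 0, 0.0, Y)


def minmax_invert(params: NormalizationParams, Y: np.ndarray) -> np.ndarray:
    """Inverse map x = y·(x_max − x_min) + x_min (constant columns → x_min)."""
    Y = np.asarray(Y, dtype=float)
    return Y * (params.xmax - params.xmin) + params.xmin
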