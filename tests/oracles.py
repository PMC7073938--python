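"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths of the package: covariance matrices
are assembled by explicit Python loops, eigenpairs come from the generic
non-symmetric eigensolver (or characteristic-polynomial root-finding), spot
means from a double loop over every pixel, and the LDA axes from an explicit
matrix inversion.
"""

from __future__ import annotations

import numpy as np


def loop_covariance(X: np.ndarray) -> np.ndarray:
    """Sample covariance (n−1 denominator) assembled entry by entry."""
    n, p = X.shape
    mean = [sum(X[i, j] for i in range(n)) / n for j in range(p)]
    C = np.zeros((p, p))
    for a in range(p):
        for b in range(p):
            C[a, b] = sum(
                (X[i, a] - mean[a]) * (X[i, b] - mean[b]) for i in range(n)
            ) / (n - 1)
    return C


def eig_descending(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Real eigenpairs of a (generic) matrix via np.linalg.eig, sorted descending."""
    evals, evecs = np.linalg.eig(M)
    evals = np.real(evals)
    evecs = np.real(evecs)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def fix_sign_columns(V: np.ndarray) -> np.ndarray:
    """Normalize columns to unit norm with largest-|entry| positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        nrm = np.linalg.norm(V[:, j])
        if nrm > 0:
            V[:, j] /= nrm
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    return V


def charpoly_eigenvalues(C: np.ndarray) -> np.ndarray:
    """Eigenvalues as roots of det(C − λI) expanded symbolically."""
    import sympy

    lam = sympy.symbols("lam")
    poly = sympy.Matrix(C).charpoly(lam)
    roots = [complex(r) for r in sympy.nroots(poly.as_expr(), n=30)]
    vals = sorted((r.real for r in roots), reverse=True)
    return np.array(vals)


def eigenvector_by_nullspace(C: np.ndarray, eigenvalue: float) -> np.ndarray:
    """Unit null vector of C − λI via the smallest right singular vector."""
    _, _, Vt = np.linalg.svd(C - eigenvalue * np.eye(C.shape[0]))
    return Vt[-1]


def brute_spot_mean(pixels: np.ndarray, center: tuple[int, int], radius: int) -> np.ndarray:
    """Per-channel disc mean by scanning every pixel of the image."""
    h, w = pixels.shape[:2]
    cr, cc = center
    total = np.zeros(3)
    count = 0
    for r in range(h):
        for c in range(w):
            if (r - cr) ** 2 + (c - cc) ** 2 <= radius**2:
                total += pixels[r, c, :].astype(float)
                count += 1
    return total / count


def lda_axes_by_inversion(
    X: np.ndarray, labels: list[str], classes: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher axes as eigenvectors of inv(Sw) @ Sb, explicit inversion."""
    k = len(classes)
    p = X.shape[1]
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        Xc = X[[lab == c for lab in labels]]
        mc = Xc.mean(axis=0)
        for row in Xc:
            d = (row - mc)[:, None]
            Sw += d @ d.T
        dm = (mc - grand)[:, None]
        Sb += Xc.shape[0] * (dm @ dm.T)
    evals, evecs = eig_descending(np.linalg.inv(Sw) @ Sb)
    s = min(k - 1, p)
    return evals[:s], fix_sign_columns(evecs[:, :s])
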