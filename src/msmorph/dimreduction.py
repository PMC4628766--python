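"""Per-fold PCA and LDA projections.

Projections are fitted on training rows only and then applied to both
training and test rows; the fold driver enforces that test rows never
reach a fitting function. The PCA percentage is interpreted as the
fraction of *dimensions* removed (93% reduction of a 52-dim space keeps
4 dimensions); LDA always projects a 4-class problem to 3 dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.decomposition import PCA


@dataclass
class Projection:
    kind: str                     # "pca" | "lda"
    center: np.ndarray            # training mean, shape (d,)
    basis: np.ndarray             # (d, k)
    k: int


def _fix_signs(basis: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (determinism)."""
    idx = np.argmax(np.abs(basis), axis=0)
    signs = np.sign(basis[idx, np.arange(basis.shape[1])])
    signs[signs == 0] = 1.0
    return basis * signs


def fit_pca(train: np.ndarray, reduction_pct: float) -> Projection:
    """Principal components keeping ``round(d*(1-pct/100))`` dimensions."""
    X = np.asarray(train, dtype=np.float64)
    d = X.shape[1]
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("zero-variance training data")
    k = max(1, int(round(d * (1.0 - reduction_pct / 100.0))))
    k = min(k, d, X.shape[0])
    model = PCA(n_components=k, svd_solver="full").fit(X)
    basis = _fix_signs(model.components_.T)
    return Projection("pca", model.mean_.copy(), basis, k)


def fit_lda(train: np.ndarray, labels: np.ndarray,
            ridge_rel: float = 1e-6) -> Projection:
    """Fisher discriminant directions, one fewer than the class count.

    The within-class scatter is regularized with a ridge of
    ``ridge_rel * trace(Sw) / d`` before solving the generalized
    eigenproblem Sb v = lambda (Sw + ridge*I) v.
    """
    X = np.asarray(train, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("LDA needs at least two classes")
    d = X.shape[1]
    mean = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        dev = Xc - mc
        Sw += dev.T @ dev
        diff = (mc - mean)[:, None]
        Sb += len(Xc) * (diff @ diff.T)
    ridge = ridge_rel * np.trace(Sw) / d
    if ridge <= 0:
        ridge = ridge_rel
    vals, vecs = eigh(Sb, Sw + ridge * np.eye(d))
    k = len(classes) - 1
    order = np.argsort(vals)[::-1][:k]
    basis = _fix_signs(vecs[:, order])
    return Projection("lda", mean, basis, k)


def apply(p: Projection, F: np.ndarray) -> np.ndarray:
    """Project rows: (x - center) @ basis."""
    F = np.atleast_2d(np.asarray(F, dtype=np.float64))
    if F.shape[1] != p.center.shape[0]:
        raise ValueError(
            f"feature width {F.shape[1]} does not match projection "
            f"input dimension {p.center.shape[0]}")
    return (F - p.center) @ p.basis
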