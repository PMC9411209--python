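"""Linear projection onto a PCA basis and unit-box scaling of embeddings.

The manifold parameters eta are obtained by projecting a (normalized) data
matrix onto the leading eigenvectors of its covariance matrix, eta = X A.
Externally computed embeddings (t-SNE, UMAP, ...) enter the pipeline as plain
coordinate tables.  Before any length-scale analysis, every manifold
coordinate is min-max scaled to [0, 1] so a kernel bandwidth sigma means the
same thing in each dimension.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .preprocess import _as_matrix

__all__ = [
    "PCAProjector",
    "UnitBoxScaler",
    "pca_basis",
    "project",
    "unit_box_scale",
]


def pca_basis(X, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Leading covariance eigenvectors of an (already normalized) matrix.

    Returns
    -------
    A : ndarray of shape (Q, q)
        Orthonormal basis, eigenvalue-ordered.  The sign of each column is
        fixed so its largest-magnitude component is positive, which makes the
        basis deterministic across eigensolvers.
    eigenvalues : ndarray of shape (q,)
        Covariance eigenvalues (ddof=1), non-increasing.
    """
    X, _ = _as_matrix(X)
    Q = X.shape[1]
    if not 1 <= q <= Q:
        raise ValueError(f"target dimension q must satisfy 1 <= q <= {Q}, got {q}")
    cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:q]
    eigvals, A = eigvals[order], eigvecs[:, order]
    # sign convention: largest-|.| component of each eigenvector positive
    flip = np.sign(A[np.abs(A).argmax(axis=0), np.arange(A.shape[1])])
    flip[flip == 0] = 1.0
    return A * flip, eigvals


def project(X, A) -> np.ndarray:
    """Linear projection ``eta = X A`` (no centering; normalize upstream)."""
    X, _ = _as_matrix(X)
    A = np.asarray(A, dtype=float)
    if X.shape[1] != A.shape[0]:
        raise ValueError(
            f"data has {X.shape[1]} columns but basis expects {A.shape[0]}"
        )
    return X @ A


def unit_box_scale(eta) -> np.ndarray:
    """Min-max scale each manifold coordinate to [0, 1]; idempotent.

    A degenerate (constant) coordinate is mapped to 0.5 everywhere with a
    warning, so it contributes zero to all pairwise distances.
    """
    eta, names = _as_matrix(eta)
    mn = eta.min(axis=0)
    rng = eta.max(axis=0) - mn
    degenerate = rng == 0
    if np.any(degenerate):
        warnings.warn(
            f"constant manifold coordinate(s) "
            f"{[names[j] for j in np.flatnonzero(degenerate)]} mapped to 0.5",
            UserWarning,
        )
    safe = np.where(degenerate, 1.0, rng)
    out = (eta - mn) / safe
    out[:, degenerate] = 0.5
    return out


class PCAProjector(TransformerMixin, BaseEstimator):
    """Project a normalized data matrix onto its leading PCA eigenvectors.

    Parameters
    ----------
    n_components : int
        Target manifold dimensionality q.

    Attributes
    ----------
    components_ : ndarray of shape (Q, q)
        Basis matrix A; ``transform`` computes ``X @ components_``.
    eigenvalues_ : ndarray of shape (q,)
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X, _ = _as_matrix(X)
        self.components_, self.eigenvalues_ = pca_basis(X, self.n_components)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        return project(X, self.components_)

    def inverse_transform(self, eta):
        check_is_fitted(self, "components_")
        return np.asarray(eta, dtype=float) @ self.components_.T


class UnitBoxScaler(TransformerMixin, BaseEstimator):
    """Min-max scale manifold coordinates to the unit box (stateless transform).

    ``transform`` rescales the matrix it is given using that matrix's own
    column extrema, matching the convention that every embedding is unit-box
    scaled in place before its cost is computed.
    """

    def fit(self, X, y=None):
        X, _ = _as_matrix(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return unit_box_scale(X)

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)
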