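"""Centering/scaling of data matrices and principal-component outlier removal.

Scaling a multivariate dataset before dimensionality reduction changes the
relative weight each state variable carries in the covariance structure, and
hence the topology of the projected manifold.  This module implements the
classical chemometrics scaling family (Auto, Pareto, VAST, Range, Level, Max,
Poisson, the bracketed 0-1 / -1-1 range scalings) plus the three
kurtosis-weighted VAST variants S1, S2 and S3.  Each scaling is defined by a
per-column center ``c_j`` and a positive scale factor ``d_j``; the normalized
column is ``(X_j - c_j) / d_j``.

Outlier removal uses the principal-component classifier: observations whose
Mahalanobis-type distance along the major PCs (those explaining the leading
half of the variance) or along the minor PCs (the trailing fifth) exceeds an
empirical quantile threshold are flagged.
"""

from __future__ import annotations

import numbers
import warnings

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, OutlierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted, check_random_state

__all__ = [
    "SCALING_NAMES",
    "ColumnScaler",
    "PCOutlierDetector",
    "compute_scaling",
    "apply_normalization",
    "invert_normalization",
    "detect_outliers",
    "subsample",
]

#: Canonical scaling names.  ``0-1`` and ``-1-1`` are accepted aliases for the
#: bracketed range scalings; matching is case-insensitive.
SCALING_NAMES = (
    "none",
    "auto",
    "pareto",
    "vast",
    "range",
    "0to1",
    "-1to1",
    "level",
    "max",
    "poisson",
    "s1",
    "s2",
    "s3",
)

_ALIASES = {
    "0-1": "0to1",
    "<0,1>": "0to1",
    "zerotoone": "0to1",
    "-1-1": "-1to1",
    "<-1,1>": "-1to1",
    "minusonetoone": "-1to1",
    "std": "auto",
}


def _canonical_name(name: str) -> str:
    token = str(name).strip().lower().replace(" ", "")
    token = _ALIASES.get(token, token)
    if token not in SCALING_NAMES:
        raise ValueError(
            f"unknown scaling {name!r}; supported: {', '.join(SCALING_NAMES)}"
        )
    return token


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    """Coerce input to a finite 2-D float array, returning column names."""
    names = None
    if hasattr(X, "columns"):
        names = [str(c) for c in X.columns]
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D data matrix, got ndim={X.ndim}")
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix contains non-finite entries")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, names


def compute_scaling(X, name: str) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate per-column centers ``c_j`` and scale factors ``d_j``.

    Parameters
    ----------
    X : array-like of shape (N, Q)
        Data matrix, one observation per row.
    name : str
        One of :data:`SCALING_NAMES` (case-insensitive; ``0-1``/``-1-1``
        aliases accepted).

    Returns
    -------
    centers, scales : ndarray of shape (Q,)
        ``d_j > 0`` is enforced; a zero or non-finite scale factor raises a
        ``ValueError`` naming the offending column.

    Notes
    -----
    Standard deviations are population (ddof=0) values and the kurtosis in
    S1-S3 is the non-excess (Pearson) fourth standardized moment, so Gaussian
    columns scale by ``k=3`` rather than zero.
    """
    X, names = _as_matrix(X)
    token = _canonical_name(name)
    Q = X.shape[1]

    mean = X.mean(axis=0)
    if token == "none":
        return np.zeros(Q), np.ones(Q)

    std = X.std(axis=0, ddof=0)
    mx = X.max(axis=0)
    mn = X.min(axis=0)
    rng = mx - mn

    with np.errstate(divide="ignore", invalid="ignore"):
        if token == "auto":
            centers, scales = mean, std
        elif token == "pareto":
            centers, scales = mean, np.sqrt(std)
        elif token == "vast":
            centers, scales = mean, std**2 / mean
        elif token == "range":
            centers, scales = mean, rng
        elif token == "0to1":
            centers, scales = mn, rng
        elif token == "-1to1":
            centers, scales = 0.5 * (mx + mn), 0.5 * rng
        elif token == "level":
            centers, scales = mean, mean
        elif token == "max":
            centers, scales = mean, mx
        elif token == "poisson":
            centers, scales = mean, np.sqrt(mean)
        else:  # s1, s2, s3
            kurt = stats.kurtosis(X, axis=0, fisher=False, bias=True)
            s2k2 = std**2 * kurt**2
            if token == "s1":
                centers, scales = mean, s2k2 / mean
            elif token == "s2":
                centers, scales = mean, s2k2 / mx
            else:
                centers, scales = mean, s2k2 / rng

    scales = np.asarray(scales, dtype=float)
    bad = ~np.isfinite(scales) | (scales <= 0)
    if np.any(bad):
        j = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"scaling {token!r} produced a zero or non-finite scale factor "
            f"for column {names[j]!r}"
        )
    return np.asarray(centers, dtype=float), scales


def apply_normalization(X, centers, scales) -> np.ndarray:
    """Return ``(X - c) / d`` column-wise."""
    X, _ = _as_matrix(X)
    centers = np.asarray(centers, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if centers.shape != (X.shape[1],) or scales.shape != (X.shape[1],):
        raise ValueError(
            f"scaling spec dimensioned for {centers.shape[0]} columns, "
            f"data has {X.shape[1]}"
        )
    return (X - centers) / scales


def invert_normalization(Xn, centers, scales) -> np.ndarray:
    """Inverse of :func:`apply_normalization`, exact to round-off."""
    Xn, _ = _as_matrix(Xn)
    return Xn * np.asarray(scales, dtype=float) + np.asarray(centers, dtype=float)


class ColumnScaler(TransformerMixin, BaseEstimator):
    """Center and scale each column of a data matrix.

    Parameters
    ----------
    method : str, default="auto"
        Scaling name (see :data:`SCALING_NAMES`).

    Attributes
    ----------
    centers_ : ndarray of shape (Q,)
    scales_ : ndarray of shape (Q,)
    n_features_in_ : int

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[1.0], [2.0], [3.0]])
    >>> ColumnScaler("level").fit(X).transform(X).ravel()
    array([-0.5,  0. ,  0.5])
    """

    def __init__(self, method: str = "auto"):
        self.method = method

    def fit(self, X, y=None):
        X, self.feature_names_in_ = _as_matrix(X)
        self.centers_, self.scales_ = compute_scaling(X, self.method)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "centers_")
        return apply_normalization(X, self.centers_, self.scales_)

    def inverse_transform(self, Xn):
        check_is_fitted(self, "centers_")
        return invert_normalization(Xn, self.centers_, self.scales_)


class PCOutlierDetector(OutlierMixin, BaseEstimator):
    """Principal-component classifier for multivariate outliers.

    The data is Auto-scaled and decomposed with PCA.  Observation ``i`` is an
    outlier if its major-PC statistic ``sum_{j<=q} z_ij^2 / L_j`` exceeds the
    empirical ``quantile`` of that statistic, or its minor-PC statistic
    ``sum_{j>=k} z_ij^2 / L_j`` exceeds the corresponding threshold, where
    ``z`` are PC scores and ``L_j`` the PCA eigenvalues.  The major set is the
    smallest leading group of PCs explaining at least
    ``major_variance_fraction`` of the variance; the minor set is the smallest
    trailing group explaining at least ``minor_variance_fraction``.

    Attributes
    ----------
    major_statistic_, minor_statistic_ : ndarray of shape (N,)
    thresholds_ : tuple (c1, c2)
    n_major_pcs_ : int
        Number of leading PCs in the major classifier.
    minor_start_ : int
        1-based index of the first PC in the minor classifier.
    outlier_indices_ : ndarray of int
    """

    def __init__(
        self,
        major_variance_fraction: float = 0.5,
        minor_variance_fraction: float = 0.2,
        quantile: float = 0.98,
    ):
        self.major_variance_fraction = major_variance_fraction
        self.minor_variance_fraction = minor_variance_fraction
        self.quantile = quantile

    def fit(self, X, y=None):
        if not 0.0 < self.quantile < 1.0:
            raise ValueError(f"quantile must lie in (0, 1), got {self.quantile}")
        X, _ = _as_matrix(X)
        N, Q = X.shape

        centers, scales = compute_scaling(X, "auto")
        Xn = apply_normalization(X, centers, scales)

        cov = np.cov(Xn, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        z = Xn @ eigvecs

        total = eigvals.sum()
        cum = np.cumsum(eigvals) / total
        q_major = int(np.searchsorted(cum, self.major_variance_fraction) + 1)
        q_major = max(1, min(q_major, Q))

        tail = np.cumsum(eigvals[::-1])[::-1] / total  # tail[j] = var of PCs j..Q
        meets = np.flatnonzero(tail >= self.minor_variance_fraction)
        k_minor = int(meets[-1] + 1) if meets.size else 1  # 1-based

        if np.any(eigvals[:q_major] <= 0) or np.any(eigvals[k_minor - 1:] <= 0):
            raise ValueError(
                "non-positive PCA eigenvalue in a classifier divisor; "
                "remove degenerate columns before outlier detection"
            )

        major = (z[:, :q_major] ** 2 / eigvals[:q_major]).sum(axis=1)
        minor = (z[:, k_minor - 1:] ** 2 / eigvals[k_minor - 1:]).sum(axis=1)
        c1 = float(np.quantile(major, self.quantile))
        c2 = float(np.quantile(minor, self.quantile))

        self.major_statistic_ = major
        self.minor_statistic_ = minor
        self.thresholds_ = (c1, c2)
        self.n_major_pcs_ = q_major
        self.minor_start_ = k_minor
        self.eigenvalues_ = eigvals
        self.outlier_indices_ = np.flatnonzero((major > c1) | (minor > c2))
        self.n_features_in_ = Q
        return self

    def predict(self, X=None):
        """Return +1 for inliers and -1 for outliers of the fitted data."""
        check_is_fitted(self, "outlier_indices_")
        labels = np.ones(self.major_statistic_.shape[0], dtype=int)
        labels[self.outlier_indices_] = -1
        return labels

    def fit_predict(self, X, y=None):
        return self.fit(X).predict()


def detect_outliers(
    X,
    major_variance_fraction: float = 0.5,
    minor_variance_fraction: float = 0.2,
    quantile: float = 0.98,
) -> PCOutlierDetector:
    """Fit a :class:`PCOutlierDetector` and return it."""
    return PCOutlierDetector(
        major_variance_fraction, minor_variance_fraction, quantile
    ).fit(X)


def subsample(X, n: int, seed=100):
    """Draw ``n`` rows uniformly without replacement; reproducible for a seed."""
    n_obs = X.shape[0]
    if not isinstance(n, numbers.Integral) or not 2 <= n <= n_obs:
        raise ValueError(f"subsample size must satisfy 2 <= n <= {n_obs}, got {n}")
    rng = check_random_state(seed)
    idx = rng.choice(n_obs, size=int(n), replace=False)
    if hasattr(X, "iloc"):
        return X.iloc[idx].reset_index(drop=True), idx
    return np.asarray(X)[idx], idx


def drop_constant_columns(df, warn: bool = True):
    """Drop zero-variance columns from a DataFrame, warning with their names."""
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant and warn:
        warnings.warn(f"dropping constant columns: {constant}", UserWarning)
    return df.drop(columns=constant)
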