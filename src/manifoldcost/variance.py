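"""Kernel-weighted normalized variance and its length-scale derivative.

For manifold parameters eta (unit-box scaled, N x q) and a dependent variable
phi, the normalized variance at bandwidth sigma is

    N(sigma) = sum_k (phi_k - K(eta_k, sigma))^2 / sum_k (phi_k - mean(phi))^2

where K is a Gaussian-kernel weighted average with weights
w_j = exp(-||eta_j - eta||^2 / sigma^2).  N(sigma) runs from ~0 (every
observation predicted by its infinitesimal neighborhood — a unique manifold)
to ~1 (smoothing at the manifold diameter erases all structure).  Its
derivative with respect to log10(sigma), shifted by the sigma -> 0 limit and
normalized by its maximum,

    D(sigma)  = dN/dlog10(sigma) + lim_{sigma->0} N(sigma)
    Dhat      = D / max(D),

peaks at the length scales where phi varies on the manifold.  The rightmost
peak sigma_peak marks the largest feature size; any mass at
sigma << sigma_peak signals small features or non-uniqueness (overlapping
states carrying different phi values).

The computation is O(m N^2) per sigma; different sigma values are independent
and processed serially here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial.distance import cdist

from .preprocess import _as_matrix

__all__ = [
    "sigma_grid",
    "kernel_estimate",
    "normalized_variance",
    "variance_derivative",
    "find_sigma_peak",
    "VarianceCurves",
]

logger = logging.getLogger(__name__)

DEFAULT_SIGMA_MIN = 1e-7
DEFAULT_SIGMA_MAX = 1e3
DEFAULT_SIGMA_NUM = 200


def sigma_grid(
    sigma_min: float = DEFAULT_SIGMA_MIN,
    sigma_max: float = DEFAULT_SIGMA_MAX,
    num: int = DEFAULT_SIGMA_NUM,
) -> np.ndarray:
    """Logarithmically spaced bandwidth grid, default ``logspace(-7, 3, 200)``."""
    if sigma_min <= 0 or sigma_max <= sigma_min:
        raise ValueError("require 0 < sigma_min < sigma_max")
    if num < 3:
        raise ValueError("sigma grid needs at least 3 points")
    return np.logspace(np.log10(sigma_min), np.log10(sigma_max), int(num))


def _phi_matrix(phi) -> tuple[np.ndarray, list[str]]:
    phi, names = _as_matrix(phi)
    variances = ((phi - phi.mean(axis=0)) ** 2).sum(axis=0)
    for j, v in enumerate(variances):
        if v == 0:
            raise ValueError(
                f"dependent variable {names[j]!r} is constant; "
                "normalized variance is undefined"
            )
    return phi, names


def kernel_estimate(query, sigma: float, eta, phi_column) -> float:
    """Gaussian-kernel weighted average of phi at one manifold location.

    Falls back to the nearest observation's value if every weight underflows
    to zero (the mathematical sigma -> 0 limit), logging the event.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    eta, _ = _as_matrix(eta)
    query = np.atleast_1d(np.asarray(query, dtype=float))
    phi_column = np.asarray(phi_column, dtype=float).ravel()
    d2 = ((eta - query) ** 2).sum(axis=1)
    w = np.exp(-d2 / sigma**2)
    total = w.sum()
    if total == 0.0:
        nearest = int(np.argmin(d2))
        logger.info(
            "all kernel weights underflowed at sigma=%g; "
            "falling back to nearest observation %d",
            sigma,
            nearest,
        )
        return float(phi_column[nearest])
    return float(w @ phi_column / total)


def normalized_variance(eta, phi, sigmas=None) -> "VarianceCurves":
    """Compute N(sigma) for each dependent variable over a bandwidth grid.

    Parameters
    ----------
    eta : array-like of shape (N, q)
        Manifold parameters, expected unit-box scaled.
    phi : array-like of shape (N, m)
        Dependent variables; each column must be non-constant.
    sigmas : ndarray, optional
        Bandwidth grid; defaults to :func:`sigma_grid`.

    Returns
    -------
    VarianceCurves
        With ``normalized_variance`` filled; call
        :func:`variance_derivative` to add D and Dhat.
    """
    eta, _ = _as_matrix(eta)
    phi, names = _phi_matrix(phi)
    if eta.shape[0] != phi.shape[0]:
        raise ValueError(
            f"eta has {eta.shape[0]} rows but phi has {phi.shape[0]}"
        )
    if sigmas is None:
        sigmas = sigma_grid()
    sigmas = np.asarray(sigmas, dtype=float)

    d2 = cdist(eta, eta, metric="sqeuclidean")
    denom = ((phi - phi.mean(axis=0)) ** 2).sum(axis=0)

    curves = np.empty((sigmas.size, phi.shape[1]))
    w = np.empty_like(d2)
    for s_idx, sigma in enumerate(sigmas):
        np.multiply(d2, -1.0 / sigma**2, out=w)
        np.exp(w, out=w)
        weight_sums = w.sum(axis=1)  # >= 1: the self-weight is exp(0)
        smoothed = (w @ phi) / weight_sums[:, None]
        curves[s_idx] = ((phi - smoothed) ** 2).sum(axis=0) / denom
    return VarianceCurves(
        sigmas=sigmas, variable_names=names, normalized_variance=curves
    )


def variance_derivative(curves: "VarianceCurves") -> "VarianceCurves":
    """Add D(sigma) and max-normalized Dhat(sigma) to a curve set.

    The derivative is taken with central finite differences on the uniform
    log10 grid (one-sided at the endpoints); the sigma -> 0 limit of N is
    approximated by its value at the smallest grid bandwidth.
    """
    N = curves.normalized_variance
    if N.shape[0] < 3:
        raise ValueError("derivative needs N(sigma) on at least 3 grid points")
    log_sigma = np.log10(curves.sigmas)
    limits = N[0].copy()
    D = np.gradient(N, log_sigma, axis=0) + limits
    D_max = D.max(axis=0)
    for j, m in enumerate(D_max):
        if m <= 0:
            raise ValueError(
                f"flat variance curve with non-positive derivative maximum "
                f"for variable {curves.variable_names[j]!r}"
            )
    curves.limit_at_zero = limits
    curves.derivative = D
    curves.normalized_derivative = D / D_max
    return curves


def find_sigma_peak(dhat, sigmas, peak_shift: float = 0.0) -> float:
    """Locate the rightmost peak of a Dhat curve; optionally shift it right.

    All local maxima are found by neighbor comparison of the discrete values
    (the rightmost index of a plateau counts as the peak location); if no
    interior local maximum exists the grid argmax is used.  With
    ``peak_shift`` p > 0 the returned scale moves toward sigma_max in log
    space: log10(sigma) = log10(sigma_peak) + p * (log10(sigma_max) -
    log10(sigma_peak)).
    """
    if not 0.0 <= peak_shift < 1.0:
        raise ValueError("peak_shift must lie in [0, 1)")
    dhat = np.asarray(dhat, dtype=float).ravel()
    sigmas = np.asarray(sigmas, dtype=float).ravel()
    peaks, props = find_peaks(dhat, plateau_size=(1, None))
    if peaks.size:
        idx = int(props["right_edges"][-1])
    else:
        idx = int(np.argmax(dhat))
    log_peak = np.log10(sigmas[idx])
    if peak_shift > 0.0:
        log_peak = log_peak + peak_shift * (np.log10(sigmas[-1]) - log_peak)
    return float(10.0**log_peak)


@dataclass
class VarianceCurves:
    """N(sigma), D(sigma) and Dhat(sigma) for a set of dependent variables.

    Arrays are shaped (n_sigmas, m); ``limit_at_zero`` holds the sigma -> 0
    limit of N per variable (approximated at the smallest grid bandwidth).
    """

    sigmas: np.ndarray
    variable_names: list[str]
    normalized_variance: np.ndarray
    limit_at_zero: np.ndarray | None = None
    derivative: np.ndarray | None = None
    normalized_derivative: np.ndarray | None = None
    sigma_peaks: dict[str, float] = field(default_factory=dict)

    @property
    def log_sigmas(self) -> np.ndarray:
        return np.log10(self.sigmas)

    def to_frame(self):
        """Export as a tidy table: sigma plus N_/Dhat_ columns per variable."""
        import pandas as pd

        data = {"sigma": self.sigmas}
        for j, name in enumerate(self.variable_names):
            data[f"N_{name}"] = self.normalized_variance[:, j]
            if self.normalized_derivative is not None:
                data[f"Dhat_{name}"] = self.normalized_derivative[:, j]
        return pd.DataFrame(data)

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)
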