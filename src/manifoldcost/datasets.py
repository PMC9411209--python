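"""Synthetic manifolds with known topology for validating the cost function.

Each generator returns ``(eta, phi)`` as pandas DataFrames: manifold
coordinates (``eta1``, ``eta2``, ... — or ``x, y, z`` for the swiss roll,
which is a data matrix to be projected) and one dependent-variable column.
Dependent variables are normalized to [0, 1].

The fixtures probe the three behaviors the cost must discriminate:

* ``gen_gaussian_bump`` — a single radial feature whose size is set by the
  Gaussian standard deviation s; cost should fall as s grows.
* ``gen_sine_superposition`` — 1 to 5 nested harmonic feature sizes
  (frequencies 2^k); cost should rise with each added scale.
* ``gen_overlap`` — a linear profile with d duplicated-location observations
  forced to phi = 0: pure non-uniqueness; cost should rise with d.
* ``gen_two_clouds`` — two labelled Gaussian clouds at a controlled
  separation; overlapping classes cost more than separated ones.
* ``gen_swiss_roll`` — the classic 3D benchmark, colored by the roll
  parameter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.datasets import make_swiss_roll
from sklearn.utils import check_random_state

__all__ = [
    "gen_gaussian_bump",
    "gen_sine_superposition",
    "gen_overlap",
    "gen_two_clouds",
    "gen_swiss_roll",
]


def _normalize01(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("cannot normalize a constant dependent variable")
    return (values - lo) / (hi - lo)


def gen_gaussian_bump(s: float = 0.2, grid_n: int = 50):
    """Radial Gaussian feature phi = exp(-(x^2+y^2)/(2 s^2)) on [-1.5, 1.5]^2.

    ``s`` in [0.05, 0.6] spans the small-to-large feature sweep; the uniform
    square grid is centered on the origin with ``grid_n`` points per axis.
    The domain half-width of 1.5 keeps even the largest bump (s = 0.6,
    ~2.5 s to the edge) from filling the square, so the feature size keeps
    growing relative to the unit box across the whole sweep.
    """
    if s <= 0:
        raise ValueError("Gaussian standard deviation s must be positive")
    if grid_n < 10:
        raise ValueError("grid_n must be at least 10")
    axis = np.linspace(-1.5, 1.5, grid_n)
    xx, yy = np.meshgrid(axis, axis, indexing="xy")
    phi = np.exp(-(xx**2 + yy**2) / (2.0 * s**2))
    eta = pd.DataFrame({"eta1": xx.ravel(), "eta2": yy.ravel()})
    return eta, pd.DataFrame({"phi": _normalize01(phi.ravel())})


def gen_sine_superposition(n_scales: int = 1, n_points: int = 1000):
    """Superposition of sines phi = sum_{k=1..n} sin(2^k x), x in [0, 10].

    Each added term halves the wavelength, introducing one more feature size.
    """
    if not 1 <= n_scales <= 5:
        raise ValueError("n_scales must lie in 1..5")
    x = np.linspace(0.0, 10.0, n_points)
    phi = np.zeros_like(x)
    for k in range(1, n_scales + 1):
        phi += np.sin(2.0**k * x)
    eta = pd.DataFrame({"eta1": x})
    return eta, pd.DataFrame({"phi": _normalize01(phi)})


def gen_overlap(d: int = 0, n_unique: int = 1000):
    """Linear profile phi = x with d overlapping observations at phi = 0.

    ``n_unique`` points are uniformly spaced on x in [0, 1] (spacing ~1e-3
    at the default resolution).  The d extra observations sit at midpoints
    between every other pair of adjacent unique points, the d occupied
    midpoints spread evenly over the whole domain, so each overlap lies
    ~5e-4 from its nearest unique neighbor while carrying phi = 0 —
    non-uniqueness whose imprint grows with d while the main feature (the
    unit gradient) is untouched.
    """
    if n_unique < 2:
        raise ValueError("n_unique must be at least 2")
    x = np.linspace(0.0, 1.0, n_unique)
    midpoints = 0.5 * (x[0:-1:2] + x[1::2])  # alternate-gap midpoints
    if not 0 <= d <= midpoints.size:
        raise ValueError(
            f"overlap depth d must lie in 0..{midpoints.size}, got {d}"
        )
    if d:
        picks = np.round(np.linspace(0, midpoints.size - 1, d)).astype(int)
        overlap_x = midpoints[picks]
    else:
        overlap_x = np.empty(0)
    eta = pd.DataFrame({"eta1": np.concatenate([x, overlap_x])})
    phi = np.concatenate([x, np.zeros(d)])
    return eta, pd.DataFrame({"phi": phi})


def gen_two_clouds(separation: float = 0.0, n_per_cloud: int = 500, seed=100):
    """Two isotropic unit-sd Gaussian clouds with 0/1 class labels as phi.

    Cloud centers sit at (-separation/2, 0) and (+separation/2, 0);
    ``separation`` is therefore measured in cloud standard deviations.
    """
    if n_per_cloud < 10:
        raise ValueError("n_per_cloud must be at least 10")
    rng = check_random_state(seed)
    half = separation / 2.0
    a = rng.normal(loc=[-half, 0.0], scale=1.0, size=(n_per_cloud, 2))
    b = rng.normal(loc=[half, 0.0], scale=1.0, size=(n_per_cloud, 2))
    pts = np.vstack([a, b])
    labels = np.concatenate(
        [np.zeros(n_per_cloud), np.ones(n_per_cloud)]
    )
    eta = pd.DataFrame({"eta1": pts[:, 0], "eta2": pts[:, 1]})
    return eta, pd.DataFrame({"label": labels})


def gen_swiss_roll(n_samples: int = 1000, seed=100):
    """Classic 3D swiss roll (t cos t, height, t sin t), t in [1.5pi, 4.5pi].

    Returns the ambient 3D coordinates as a data matrix and the roll
    parameter t (normalized to [0, 1]) as the dependent variable.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    coords, t = make_swiss_roll(n_samples=n_samples, random_state=seed)
    data = pd.DataFrame(coords, columns=["x", "y", "z"])
    return data, pd.DataFrame({"t": _normalize01(t)})
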