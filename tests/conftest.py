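import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def brute_force_normalized_variance(eta, phi, sigmas):
    """Independent O(N^2) double-loop evaluation of N(sigma).

    Deliberately written with explicit Python loops over observations so it
    shares no code path with the production implementation.
    """
    eta = np.asarray(eta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if eta.ndim == 1:
        eta = eta[:, None]
    if phi.ndim == 1:
        phi = phi[:, None]
    n, m = phi.shape
    out = np.empty((len(sigmas), m))
    for s_idx, sigma in enumerate(sigmas):
        for i in range(m):
            col = phi[:, i]
            denom = sum((col[k] - col.mean()) ** 2 for k in range(n))
            num = 0.0
            for k in range(n):
                wsum = 0.0
                vsum = 0.0
                for j in range(n):
                    diff = eta[j] - eta[k]
                    w = np.exp(-(diff @ diff) / sigma**2)
                    wsum += w
                    vsum += w * col[j]
                num += (col[k] - vsum / wsum) ** 2
            out[s_idx, i] = num / denom
    return out


@pytest.fixture(scope="session")
def small_manifold():
    """A 40-point 2D manifold with a smooth dependent variable."""
    gen = np.random.default_rng(42)
    eta = gen.uniform(size=(40, 2))
    phi = np.sin(3 * eta[:, 0]) + eta[:, 1] ** 2
    return eta, phi[:, None]
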