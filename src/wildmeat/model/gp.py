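"""Latent Gaussian process over inter-location distances.

The spatial similarity between locations decays with distance through an
exponentiated-quadratic kernel: ``X[l, j] = zeta^2 exp(-rho^2 D[l, j]^2)``
with a small jitter ``delta`` on the diagonal to keep the matrix positive
definite.  ``zeta`` is the marginal standard deviation (maximum covariance
between sites) and ``rho`` the inverse length scale (rate of decay).  The
latent effect is built non-centred as ``eps = LX @ eta`` with ``eta``
standard normal and ``LX`` the Cholesky factor of ``X``.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular

DEFAULT_JITTER = 1e-9


def gp_kernel(zeta: float, rho: float, D: np.ndarray) -> np.ndarray:
    """Exponentiated-quadratic covariance without the diagonal jitter."""
    return zeta**2 * np.exp(-(rho**2) * D**2)


def gp_build(
    zeta: float, rho: float, D: np.ndarray, delta: float = DEFAULT_JITTER
) -> tuple[np.ndarray, np.ndarray]:
    """Covariance matrix and its Cholesky factor for distances ``D`` (km).

    Raises a ``LinAlgError`` suggesting a larger jitter if the factorization
    fails; the jitter is never enlarged silently.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square matrix")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("D must be symmetric with a zero diagonal")
    X = gp_kernel(zeta, rho, D)
    X[np.diag_indices_from(X)] += delta
    try:
        LX = np.linalg.cholesky(X)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"Cholesky factorization failed at jitter delta={delta:g}; "
            "consider a larger jitter"
        ) from err
    return X, LX


def chol_diff(L: np.ndarray, dX: np.ndarray) -> np.ndarray:
    """Differential of a Cholesky factor: dL for X = L L^T and given dX.

    Uses dL = L * Phi(L^-1 dX L^-T), where Phi keeps the lower triangle and
    halves the diagonal.
    """
    A = solve_triangular(L, dX, lower=True)
    A = solve_triangular(L, A.T, lower=True).T
    Phi = np.tril(A)
    Phi[np.diag_indices_from(Phi)] *= 0.5
    return L @ Phi
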