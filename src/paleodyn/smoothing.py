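"""Cubic smoothing splines with an R-style ``spar`` parametrisation.

The smoother minimises ``sum_i (y_i - f(t_i))^2 + lambda * int f''(u)^2 du``
over natural cubic splines with knots at every observation, with the abscissa
rescaled to [0, 1]. The user-facing smoothness knob is ``spar`` in [0, 1],
mapped to the penalty weight by

    lambda = r * 256**(3*spar - 1),      r = tr(design) / tr(penalty)

so that printed ``spar`` values from standard statistical software carry over
meaningfully. In the value basis used here the design matrix is the identity
(trace n) and the penalty matrix is the Green-Silverman matrix
``K = Q R^{-1} Q^T`` with ``f^T K f = int f''^2``.

The production solve delegates to :func:`scipy.interpolate.make_smoothing_spline`,
which solves the identical penalised criterion in O(n) banded form; the dense
``(I + lambda K)^{-1} y`` solve is exposed for cross-checking.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.linalg import solve_banded

from .errors import ValidationError

__all__ = [
    "penalty_matrices",
    "penalty_trace",
    "spar_to_lambda",
    "smooth_series",
    "dense_spline_solve",
]


def _check_grid(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.size < 4:
        raise ValidationError("smoothing spline needs >= 4 points")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("grid must be strictly increasing")
    return t


def penalty_matrices(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Green-Silverman Q (n x n-2) and R (n-2 x n-2) for knots ``u``."""
    u = np.asarray(u, dtype=float)
    n = u.size
    h = np.diff(u)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        k = j - 1
        Q[j - 1, k] = 1.0 / h[j - 1]
        Q[j, k] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, k] = 1.0 / h[j]
        R[k, k] = (h[j - 1] + h[j]) / 3.0
        if k + 1 < n - 2:
            R[k, k + 1] = R[k + 1, k] = h[j] / 6.0
    return Q, R


def penalty_trace(u: np.ndarray) -> float:
    """tr(K) with K = Q R^{-1} Q^T, via a banded solve of R Z = Q^T Q.

    Q and R are sparse (tridiagonal structure), so Q^T Q is assembled in
    sparse form; cost is O(n^2) from the banded solve only.
    """
    u = np.asarray(u, dtype=float)
    n = u.size
    h = np.diff(u)
    a = 1.0 / h[:-1]  # Q[j-1, k]
    b = -1.0 / h[:-1] - 1.0 / h[1:]  # Q[j, k]
    c = 1.0 / h[1:]  # Q[j+1, k]
    rows = np.concatenate([np.arange(n - 2), np.arange(1, n - 1), np.arange(2, n)])
    cols = np.tile(np.arange(n - 2), 3)
    vals = np.concatenate([a, b, c])
    from scipy.sparse import coo_matrix

    Q = coo_matrix((vals, (rows, cols)), shape=(n, n - 2)).tocsc()
    QtQ = (Q.T @ Q).toarray()
    m = n - 2
    ab = np.zeros((3, m))
    diag = (h[:-1] + h[1:]) / 3.0
    off = h[1:-1] / 6.0
    ab[0, 1:] = off
    ab[1, :] = diag
    ab[2, :-1] = off
    Z = solve_banded((1, 1), ab, QtQ)
    return float(np.trace(Z))


_lambda_cache: dict[tuple[bytes, float], float] = {}


def spar_to_lambda(t: np.ndarray, spar: float) -> float:
    """Map ``spar`` in [0, 1] to the penalty weight on the [0, 1]-scaled grid."""
    if not 0.0 <= spar <= 1.0:
        raise ValidationError(f"spar must be in [0, 1], got {spar}")
    t = _check_grid(t)
    key = (t.tobytes(), float(spar))
    if key not in _lambda_cache:
        u = (t - t[0]) / (t[-1] - t[0])
        r = t.size / penalty_trace(u)
        _lambda_cache[key] = r * 256.0 ** (3.0 * spar - 1.0)
    return _lambda_cache[key]


def smooth_series(
    t: np.ndarray, y: np.ndarray, spar: float | None = None, lam: float | None = None
) -> np.ndarray:
    """Fitted spline values at the input grid, smoothness set by spar or lam.

    ``lam`` (if given) is the penalty weight on the [0, 1]-rescaled abscissa
    and overrides ``spar``.
    """
    t = _check_grid(t)
    y = np.asarray(y, dtype=float)
    if y.shape != t.shape:
        raise ValidationError("t/y length mismatch")
    if lam is None:
        if spar is None:
            raise ValidationError("provide spar or lam")
        lam = spar_to_lambda(t, spar)
    u = (t - t[0]) / (t[-1] - t[0])
    return np.asarray(make_smoothing_spline(u, y, lam=lam)(u))


def dense_spline_solve(t: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Direct dense solve of (I + lam*K) f = y on the rescaled grid.

    Independent of :func:`smooth_series`'s banded path; intended for
    cross-validation at small n.
    """
    t = _check_grid(t)
    y = np.asarray(y, dtype=float)
    u = (t - t[0]) / (t[-1] - t[0])
    Q, R = penalty_matrices(u)
    K = Q @ np.linalg.solve(R, Q.T)
    return np.linalg.solve(np.eye(t.size) + lam * K, y)
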