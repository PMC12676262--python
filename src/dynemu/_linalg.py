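"""Shared positive-definite linear algebra helpers.

All log-determinants and quadratic forms go through Cholesky factors;
no explicit matrix inverses are formed anywhere in the package.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

__all__ = [
    "symmetrize",
    "chol_lower",
    "chol_logdet",
    "chol_solve",
    "inv_quad",
]

#: Jitter ladder used before declaring a matrix numerically non-PD.
_JITTERS = (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6)


def symmetrize(a: np.ndarray) -> np.ndarray:
    """Return (A + Aᵀ)/2."""
    return 0.5 * (a + a.T)


def chol_lower(a: np.ndarray, jitter: bool = True) -> np.ndarray:
    """Lower Cholesky factor of an SPD matrix.

    Symmetrizes first and, if ``jitter``, retries with adaptive diagonal
    jitter from 1e-10 up to 1e-6 (scaled by the mean diagonal) before
    raising ``numpy.linalg.LinAlgError``.
    """
    a = symmetrize(np.asarray(a, dtype=float))
    try:  # fast path: numpy avoids scipy's finite-checking overhead
        return np.linalg.cholesky(a)
    except np.linalg.LinAlgError:
        if not jitter:
            raise
    scale = max(np.mean(np.abs(np.diag(a))), 1.0)
    eye = np.eye(a.shape[0])
    err: Exception | None = None
    for eps in _JITTERS[1:]:
        try:
            return cholesky(a + eps * scale * eye, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare path
            err = exc
    raise np.linalg.LinAlgError(
        f"matrix of order {a.shape[0]} is not positive definite "
        f"even after jitter up to {_JITTERS[-1]:g}"
    ) from err


def chol_logdet(chol: np.ndarray) -> float:
    """log det(A) from a lower Cholesky factor of A."""
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def chol_solve(chol: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve A x = b given the lower Cholesky factor of A."""
    return cho_solve((chol, True), b, check_finite=False)


def inv_quad(chol: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Compute xᵀ A⁻¹ x (matrix-valued) via triangular solves."""
    w = solve_triangular(chol, x, lower=True, check_finite=False)
    return w.T @ w
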