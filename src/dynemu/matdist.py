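"""Matrix-variate distribution layer.

Samplers and log-densities for the matrix-normal, inverse-Wishart,
matrix-normal-inverse-Wishart (MNIW), matrix-normal-inverse-gamma (MNIG),
hyper-T and hyper-T-scalar families used throughout the dynamic emulator.

Parameterization conventions
----------------------------
* ``MN(m, M, S)``: mean ``m`` (p x S), row covariance ``M`` (p x p), column
  covariance ``S`` (S x S); ``vec`` form has covariance ``S (x) M``.
* ``IW(n, D)``: density proportional to
  ``det(D)^{n/2} det(Sigma)^{-(n+S+1)/2} exp(-tr(D Sigma^{-1})/2)``; proper
  for ``n > S - 1``.  This is *not* the canonical matrix-T dof; use
  :func:`canonical_matrix_t_dof` to convert.
* ``HT(m, M, n, D)``: Sigma-marginal of the MNIW; entry (i, j) has a
  univariate-t margin with dof ``nu = n - S + 1``, mean ``m_ij`` and scale
  ``sqrt(M_ii D_jj / nu)`` (variance ``M_ii D_jj / (n - S - 1)``).
* ``HTs(m, M, n, d, R)``: sigma^2-marginal of the MNIG with fixed column
  correlation ``R``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, multigammaln
from scipy.stats import invwishart
from scipy.linalg import solve_triangular

from ._linalg import chol_logdet, chol_lower, inv_quad, symmetrize

__all__ = [
    "MatrixNormalParams",
    "MNIWState",
    "MNIGState",
    "canonical_matrix_t_dof",
    "sample_matrix_normal",
    "logpdf_matrix_normal",
    "sample_inverse_wishart",
    "sample_inverse_gamma",
    "logpdf_hyper_t",
    "sample_hyper_t",
    "logpdf_hyper_t_scalar",
    "sample_hyper_t_scalar",
    "sample_mniw",
    "sample_mnig",
]


@dataclass(frozen=True)
class MatrixNormalParams:
    """Parameters (mean, row covariance, column covariance) of a matrix normal."""

    mean: np.ndarray
    row_cov: np.ndarray
    col_cov: np.ndarray

    def __post_init__(self) -> None:
        p, s = np.shape(self.mean)
        if np.shape(self.row_cov) != (p, p) or np.shape(self.col_cov) != (s, s):
            raise ValueError(
                "non-conformal matrix-normal parameters: mean "
                f"{np.shape(self.mean)}, row_cov {np.shape(self.row_cov)}, "
                f"col_cov {np.shape(self.col_cov)}"
            )


@dataclass(frozen=True)
class MNIWState:
    """Conjugate matrix-normal-inverse-Wishart posterior parameters (m, M, n, D)."""

    m: np.ndarray
    M: np.ndarray
    n: float
    D: np.ndarray

    def __post_init__(self) -> None:
        p, s = np.shape(self.m)
        if np.shape(self.M) != (p, p) or np.shape(self.D) != (s, s):
            raise ValueError("non-conformal MNIW state")
        if self.n <= s - 1:
            raise ValueError(f"inverse-Wishart dof n={self.n} must exceed S-1={s - 1}")

    @property
    def shape(self) -> tuple[int, int]:
        return np.shape(self.m)


@dataclass(frozen=True)
class MNIGState:
    """Matrix-normal-inverse-gamma state: (m, M, shape, rate) with fixed correlation R."""

    m: np.ndarray
    M: np.ndarray
    n_shape: float
    d_rate: float
    R: np.ndarray

    def __post_init__(self) -> None:
        p, s = np.shape(self.m)
        if np.shape(self.M) != (p, p) or np.shape(self.R) != (s, s):
            raise ValueError("non-conformal MNIG state")
        if self.n_shape <= 0 or self.d_rate <= 0:
            raise ValueError("MNIG shape and rate must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return np.shape(self.m)


def canonical_matrix_t_dof(n: float, s: int) -> float:
    """Canonical matrix-T dof implied by inverse-Wishart dof ``n`` at dimension ``s``."""
    return n - s + 1


# ---------------------------------------------------------------------------
# matrix normal
# ---------------------------------------------------------------------------

def sample_matrix_normal(
    mean: np.ndarray,
    chol_row: np.ndarray,
    chol_col: np.ndarray,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw from MN(mean, M, S) given lower Cholesky factors of M and S.

    ``Theta = m + L_M Z L_S^T`` with ``Z`` i.i.d. standard normal.  With
    ``size`` an int, returns a ``(size, p, S)`` stack of draws.
    """
    mean = np.asarray(mean, dtype=float)
    p, s = mean.shape
    if np.shape(chol_row) != (p, p) or np.shape(chol_col) != (s, s):
        raise ValueError(
            f"non-conformal Cholesky factors for a {p}x{s} matrix normal"
        )
    shape = (p, s) if size is None else (size, p, s)
    z = rng.standard_normal(shape)
    return mean + chol_row @ z @ chol_col.T


def logpdf_matrix_normal(x: np.ndarray, params: MatrixNormalParams) -> float:
    """Log-density of MN(mean, row_cov, col_cov) at ``x``."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(params.mean, dtype=float)
    if x.shape != m.shape:
        raise ValueError(f"x shape {x.shape} != mean shape {m.shape}")
    p, s = m.shape
    lm = chol_lower(params.row_cov)
    ls = chol_lower(params.col_cov)
    # tr(S^-1 (X-m)^T M^-1 (X-m)) via double triangular solve
    a = solve_triangular(lm, x - m, lower=True)
    b = solve_triangular(ls, a.T, lower=True)
    quad = float(np.sum(b * b))
    return -0.5 * (
        p * s * np.log(2.0 * np.pi)
        + s * chol_logdet(lm)
        + p * chol_logdet(ls)
        + quad
    )


# ---------------------------------------------------------------------------
# inverse Wishart / inverse gamma
# ---------------------------------------------------------------------------

def sample_inverse_wishart(
    n: float, D: np.ndarray, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw from IW(n, D) in the scale-D parameterization (see module docstring)."""
    D = np.asarray(D, dtype=float)
    s = D.shape[0]
    if n <= s - 1:
        raise ValueError(f"inverse-Wishart dof n={n} must exceed S-1={s - 1}")
    draw = invwishart.rvs(df=n, scale=symmetrize(D), size=1 if size is None else size,
                          random_state=rng)
    draw = np.asarray(draw, dtype=float).reshape(-1, s, s)
    return draw[0] if size is None else draw


def sample_inverse_gamma(
    shape: float, rate: float, rng: np.random.Generator, size: int | None = None
):
    """Draw sigma^2 ~ IG(shape, rate) (density ∝ x^{-shape-1} e^{-rate/x})."""
    if shape <= 0 or rate <= 0:
        raise ValueError("inverse-gamma shape and rate must be positive")
    g = rng.gamma(shape, 1.0 / rate, size=size)
    return 1.0 / g


# ---------------------------------------------------------------------------
# hyper-T (Sigma-marginal of the MNIW)
# ---------------------------------------------------------------------------

def logpdf_hyper_t(
    x: np.ndarray, m: np.ndarray, M: np.ndarray, n: float, D: np.ndarray
) -> float:
    """Log-density of HT(m, M, n, D) at ``x``.

    ``p(X) = Gamma_S((n+p)/2) det(I_S + D^{-1} (X-m)^T M^{-1} (X-m))^{-(n+p)/2}
    / [pi^{pS/2} Gamma_S(n/2) det(M)^{S/2} det(D)^{p/2}]``
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    p, s = m.shape
    if x.shape != (p, s):
        raise ValueError(f"x shape {x.shape} != ({p}, {s})")
    if n <= s - 1:
        raise ValueError(f"hyper-T requires n > S-1; got n={n}, S={s}")
    lm = chol_lower(M)
    ld = chol_lower(D)
    q = inv_quad(lm, x - m)  # (X-m)^T M^-1 (X-m), S x S
    # det(I + D^-1 Q) = det(D + Q)/det(D); use Cholesky of D + Q (SPD)
    ldq = chol_lower(D + q)
    return (
        multigammaln(0.5 * (n + p), s)
        - multigammaln(0.5 * n, s)
        - 0.5 * p * s * np.log(np.pi)
        - 0.5 * s * chol_logdet(lm)
        - 0.5 * p * chol_logdet(ld)
        - 0.5 * (n + p) * (chol_logdet(ldq) - chol_logdet(ld))
    )


def sample_hyper_t(
    m: np.ndarray,
    M: np.ndarray,
    n: float,
    D: np.ndarray,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw from HT(m, M, n, D) by composition: Sigma ~ IW(n, D), X ~ MN(m, M, Sigma)."""
    m = np.asarray(m, dtype=float)
    lm = chol_lower(M)
    if size is None:
        sigma = sample_inverse_wishart(n, D, rng)
        return sample_matrix_normal(m, lm, chol_lower(sigma), rng)
    out = np.empty((size,) + m.shape)
    sigmas = sample_inverse_wishart(n, D, rng, size=size)
    for i in range(size):
        out[i] = sample_matrix_normal(m, lm, chol_lower(sigmas[i]), rng)
    return out


# ---------------------------------------------------------------------------
# hyper-T-scalar (sigma^2-marginal of the MNIG)
# ---------------------------------------------------------------------------

def logpdf_hyper_t_scalar(
    x: np.ndarray,
    m: np.ndarray,
    M: np.ndarray,
    n_shape: float,
    d_rate: float,
    R: np.ndarray,
) -> float:
    """Log-density of HTs(m, M, n, d, R) at ``x`` (sigma^2 marginalized out).

    ``p(X) = Gamma(pS/2 + n)/Gamma(n) (2 pi d)^{-pS/2} det(M)^{-S/2}
    det(R)^{-p/2} [1 + tr(R^{-1}(X-m)^T M^{-1}(X-m))/(2d)]^{-(pS/2+n)}``
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    p, s = m.shape
    if x.shape != (p, s):
        raise ValueError(f"x shape {x.shape} != ({p}, {s})")
    if n_shape <= 0 or d_rate <= 0:
        raise ValueError("n_shape and d_rate must be positive")
    lm = chol_lower(M)
    lr = chol_lower(R)
    a = solve_triangular(lm, x - m, lower=True)
    b = solve_triangular(lr, a.T, lower=True)
    quad = float(np.sum(b * b))  # tr(R^-1 (X-m)^T M^-1 (X-m))
    half_ps = 0.5 * p * s
    return (
        gammaln(half_ps + n_shape)
        - gammaln(n_shape)
        - half_ps * np.log(2.0 * np.pi * d_rate)
        - 0.5 * s * chol_logdet(lm)
        - 0.5 * p * chol_logdet(lr)
        - (half_ps + n_shape) * np.log1p(quad / (2.0 * d_rate))
    )


def sample_hyper_t_scalar(
    m: np.ndarray,
    M: np.ndarray,
    n_shape: float,
    d_rate: float,
    R: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw from HTs by composition: sigma^2 ~ IG(n, d), X ~ MN(m, M, sigma^2 R)."""
    sig2 = float(sample_inverse_gamma(n_shape, d_rate, rng))
    return sample_matrix_normal(
        np.asarray(m, dtype=float), chol_lower(M), np.sqrt(sig2) * chol_lower(R), rng
    )


# ---------------------------------------------------------------------------
# joint conjugate families
# ---------------------------------------------------------------------------

def sample_mniw(state: MNIWState, rng: np.random.Generator):
    """Draw (Theta, Sigma) from MNIW(m, M, n, D)."""
    sigma = sample_inverse_wishart(state.n, state.D, rng)
    theta = sample_matrix_normal(state.m, chol_lower(state.M), chol_lower(sigma), rng)
    return theta, sigma


def sample_mnig(state: MNIGState, rng: np.random.Generator):
    """Draw (Theta, sigma^2) from MNIG(m, M, n, d; R)."""
    sig2 = float(sample_inverse_gamma(state.n_shape, state.d_rate, rng))
    theta = sample_matrix_normal(
        state.m, chol_lower(state.M), np.sqrt(sig2) * chol_lower(state.R), rng
    )
    return theta, sig2
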