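"""Exact forward filtering, backward smoothing/sampling and predictives
for matrix-variate dynamic linear models.

Two conjugate paths are supported:

* MNIW: unstructured column covariance ``Sigma ~ IW(n, D)``;
* MNIG: ``Sigma = sigma^2 R`` with fixed correlation ``R`` and
  ``sigma^2 ~ IG(n, d)``.

Both share the first/second-moment recursions

    a_t = G_t m_{t-1};            A_t = G_t M_{t-1} G_t^T + W_t
    q_t = F_t a_t;                Q_t = F_t A_t F_t^T + V_t
    m_t = a_t + A_t F_t^T Q_t^{-1} (Y_t - q_t)
    M_t = A_t - A_t F_t^T Q_t^{-1} F_t A_t

and differ only in the scale bookkeeping (``n_t``/``D_t`` vs ``n_t``/``d_t``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular

from ._linalg import chol_lower, chol_solve, inv_quad, symmetrize
from .matdist import MNIGState, MNIWState

__all__ = [
    "DLMSpec",
    "FilterOutput",
    "SmoothedMoments",
    "FFBSResult",
    "forward_filter",
    "backward_moments",
    "ffbs",
    "predictive_conditional",
    "predictive_hyper_t_moments",
]


def _as_seq(x, T: int) -> list[np.ndarray]:
    """Broadcast a single matrix to a length-T list; pass sequences through."""
    if isinstance(x, np.ndarray):
        return [x] * T
    x = list(x)
    if len(x) != T:
        raise ValueError(f"expected {T} per-time matrices, got {len(x)}")
    return x


@dataclass
class DLMSpec:
    """Matrix-variate DLM specification.

    ``F``, ``G``, ``V``, ``W`` may each be a single array (constant over time)
    or a length-T sequence.  ``prior`` selects the conjugate path: an
    :class:`~dynemu.matdist.MNIWState` or :class:`~dynemu.matdist.MNIGState`.
    """

    F: Sequence[np.ndarray] | np.ndarray
    G: Sequence[np.ndarray] | np.ndarray
    V: Sequence[np.ndarray] | np.ndarray
    W: Sequence[np.ndarray] | np.ndarray
    prior: MNIWState | MNIGState
    T: int

    def __post_init__(self) -> None:
        self.F = _as_seq(self.F, self.T)
        self.G = _as_seq(self.G, self.T)
        self.V = _as_seq(self.V, self.T)
        self.W = _as_seq(self.W, self.T)
        p_prev = self.prior.shape[0]
        for t in range(self.T):
            n_t, p_t = self.F[t].shape
            if self.G[t].shape != (p_t, p_prev):
                raise ValueError(f"G at t={t + 1} must be {p_t}x{p_prev}")
            if self.V[t].shape != (n_t, n_t) or self.W[t].shape != (p_t, p_t):
                raise ValueError(f"non-conformal V/W at t={t + 1}")
            p_prev = p_t

    @property
    def is_mnig(self) -> bool:
        return isinstance(self.prior, MNIGState)


@dataclass
class FilterOutput:
    """Per-time filtering quantities; index 0 holds the prior (m0, M0, n0, D0/d0)."""

    a: list  # prior means, a[0] is None
    A: list
    q: list  # one-step forecast means, q[0] is None
    Q: list
    m: list
    M: list
    n: list
    D: list | None = None  # MNIW scale matrices
    d: list | None = None  # MNIG rates
    cholQ: list = field(default_factory=list)

    @property
    def T(self) -> int:
        return len(self.m) - 1

    @property
    def is_mnig(self) -> bool:
        return self.d is not None

    def terminal_state(self):
        if self.is_mnig:
            return self.n[-1], self.d[-1]
        return self.n[-1], self.D[-1]


@dataclass
class SmoothedMoments:
    """Marginal smoothed moments h_t (p x S) and H_t (p x p), t = 0..T."""

    h: list
    H: list


@dataclass
class FFBSResult:
    """Joint posterior draws plus the filter/smoother summaries they came from."""

    thetas: list  # length L; each a list of T+1 (p_t x S) matrices
    sigmas: np.ndarray | None  # (L, S, S) for MNIW
    sigma2: np.ndarray | None  # (L,) for MNIG
    filter_out: FilterOutput
    smoothed: SmoothedMoments

    @property
    def L(self) -> int:
        return len(self.thetas)

    def theta_array(self) -> np.ndarray:
        """Stack draws to a (draw, time, p, S) array (constant dims only)."""
        return np.asarray([np.asarray(th) for th in self.thetas])


def forward_filter(Y: Sequence[np.ndarray], spec: DLMSpec) -> FilterOutput:
    """Run the exact conjugate forward filter (MNIW or MNIG path)."""
    Y = [np.asarray(y, dtype=float) for y in Y]
    if len(Y) != spec.T:
        raise ValueError(f"expected {spec.T} observation matrices, got {len(Y)}")
    mnig = spec.is_mnig
    prior = spec.prior
    out = FilterOutput(
        a=[None], A=[None], q=[None], Q=[None],
        m=[np.asarray(prior.m, dtype=float)],
        M=[np.asarray(prior.M, dtype=float)],
        n=[prior.n_shape if mnig else prior.n],
        D=None if mnig else [np.asarray(prior.D, dtype=float)],
        d=[prior.d_rate] if mnig else None,
        cholQ=[None],
    )
    chol_r = chol_lower(prior.R) if mnig else None
    for t in range(spec.T):
        F, G, V, W = spec.F[t], spec.G[t], spec.V[t], spec.W[t]
        y = Y[t]
        n_rows, s_cols = y.shape
        if F.shape[0] != n_rows:
            raise ValueError(f"Y at t={t + 1} has {n_rows} rows but F has {F.shape[0]}")
        a = G @ out.m[-1]
        A = symmetrize(G @ out.M[-1] @ G.T + W)
        q = F @ a
        Q = symmetrize(F @ A @ F.T + V)
        try:
            cq = chol_lower(Q)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"forecast covariance Q not positive definite at t={t + 1}"
            ) from exc
        resid = y - q
        AFt = A @ F.T
        m = a + AFt @ chol_solve(cq, resid)
        M = symmetrize(A - AFt @ chol_solve(cq, AFt.T))
        out.a.append(a)
        out.A.append(A)
        out.q.append(q)
        out.Q.append(Q)
        out.cholQ.append(cq)
        out.m.append(m)
        out.M.append(M)
        if mnig:
            w = solve_triangular(cq, resid, lower=True)
            v = solve_triangular(chol_r, w.T, lower=True)
            out.n.append(out.n[-1] + n_rows * s_cols / 2.0)
            out.d.append(out.d[-1] + 0.5 * float(np.sum(v * v)))
        else:
            out.n.append(out.n[-1] + n_rows)
            out.D.append(symmetrize(out.D[-1] + inv_quad(cq, resid)))
    return out


def backward_moments(filter_out: FilterOutput, spec: DLMSpec) -> SmoothedMoments:
    """Marginal smoothed moments via the backward recursion

    h_t = m_t + M_t G_{t+1}^T A_{t+1}^{-1} (h_{t+1} - a_{t+1})
    H_t = M_t - M_t G_{t+1}^T A_{t+1}^{-1} (A_{t+1} - H_{t+1}) A_{t+1}^{-1} G_{t+1} M_t
    """
    T = filter_out.T
    h = [None] * (T + 1)
    H = [None] * (T + 1)
    h[T] = filter_out.m[T]
    H[T] = filter_out.M[T]
    for t in range(T - 1, -1, -1):
        G_next = spec.G[t]  # spec.G[t] maps Theta_t -> Theta_{t+1}
        A_next = filter_out.A[t + 1]
        try:
            ca = chol_lower(A_next)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"prior covariance A not positive definite at t={t + 1}"
            ) from exc
        B = (chol_solve(ca, G_next @ filter_out.M[t])).T  # M_t G^T A^{-1}
        h[t] = filter_out.m[t] + B @ (h[t + 1] - filter_out.a[t + 1])
        H[t] = symmetrize(filter_out.M[t] - B @ (A_next - H[t + 1]) @ B.T)
    return SmoothedMoments(h=h, H=H)


def _backward_gain_and_noise(filter_out: FilterOutput, spec: DLMSpec):
    """Per-time gain B_t and conditional row-cov Cholesky for backward sampling."""
    T = filter_out.T
    gains = [None] * T
    chol_cond = [None] * T
    degenerate = [False] * T
    for t in range(T):
        G_next = spec.G[t]
        ca = chol_lower(filter_out.A[t + 1])
        B = (chol_solve(ca, G_next @ filter_out.M[t])).T
        C = symmetrize(filter_out.M[t] - B @ G_next @ filter_out.M[t])
        gains[t] = B
        scale = max(float(np.max(np.abs(np.diag(filter_out.M[t]))) if C.size else 0.0), 1.0)
        if float(np.max(np.abs(C))) <= 1e-12 * scale:
            degenerate[t] = True
            chol_cond[t] = np.zeros_like(C)
        else:
            chol_cond[t] = chol_lower(C)
    return gains, chol_cond, degenerate


def ffbs(
    Y: Sequence[np.ndarray],
    spec: DLMSpec,
    L: int,
    rng: np.random.Generator,
    fixed_sigma: np.ndarray | None = None,
) -> FFBSResult:
    """Draw L joint samples from the exact posterior over (Theta_{0:T}, Sigma).

    Forward filter once, compute the backward gains and conditional covariances
    once, then sample each path Theta_T, Theta_{T-1}, ..., Theta_0 from the
    sequential conditionals (shared column covariance per draw).  With
    ``fixed_sigma`` the column covariance is held at the given matrix (the
    Sigma = I reference structure) instead of being sampled.
    """
    if L < 1:
        raise ValueError("draw count L must be >= 1")
    fo = forward_filter(Y, spec)
    sm = backward_moments(fo, spec)
    T = fo.T
    mnig = fo.is_mnig
    s_cols = spec.prior.shape[1]

    if fixed_sigma is not None:
        cf = chol_lower(np.asarray(fixed_sigma, dtype=float))
        chol_cols = np.broadcast_to(cf, (L,) + cf.shape)
        sigmas, sig2 = None, None
    elif mnig:
        from .matdist import sample_inverse_gamma

        sig2 = np.asarray(sample_inverse_gamma(fo.n[-1], fo.d[-1], rng, size=L))
        chol_r = chol_lower(spec.prior.R)
        chol_cols = np.sqrt(sig2)[:, None, None] * chol_r[None, :, :]
        sigmas = None
    else:  # MNIW
        from .matdist import sample_inverse_wishart

        sigmas = sample_inverse_wishart(fo.n[-1], fo.D[-1], rng, size=L)
        chol_cols = np.linalg.cholesky(sigmas)
        sig2 = None

    gains, chol_cond, degenerate = _backward_gain_and_noise(fo, spec)

    # terminal draws, batched over L
    cm = chol_lower(fo.M[T])
    pT = fo.m[T].shape[0]
    z = rng.standard_normal((L, pT, s_cols))
    theta_next = fo.m[T][None] + cm @ z @ np.transpose(chol_cols, (0, 2, 1))

    paths = [[None] * (T + 1) for _ in range(L)]
    for l in range(L):
        paths[l][T] = theta_next[l]
    for t in range(T - 1, -1, -1):
        B, cc = gains[t], chol_cond[t]
        mean = fo.m[t][None] + np.einsum(
            "ij,ljk->lik", B, theta_next - fo.a[t + 1][None]
        )
        if degenerate[t]:
            theta_next = mean
        else:
            z = rng.standard_normal((L, cc.shape[0], s_cols))
            theta_next = mean + cc @ z @ np.transpose(chol_cols, (0, 2, 1))
        for l in range(L):
            paths[l][t] = theta_next[l]
    return FFBSResult(thetas=paths, sigmas=sigmas, sigma2=sig2, filter_out=fo, smoothed=sm)


# ---------------------------------------------------------------------------
# predictive distributions at new inputs
# ---------------------------------------------------------------------------

_DEGENERATE_TOL = 1e-10


def predictive_conditional(
    F_new: np.ndarray,
    J: np.ndarray,
    V_new: np.ndarray,
    theta: np.ndarray,
    chol_col: np.ndarray,
    Y: np.ndarray,
    F: np.ndarray,
    V: np.ndarray,
    rng: np.random.Generator,
    return_moments: bool = False,
):
    """Draw Y_new ~ MN(F_new Theta + J^T V^{-1}(Y - F Theta), V_new - J^T V^{-1} J, Sigma)
    given one posterior draw (theta, column-cov Cholesky ``chol_col``).

    When the conditional row covariance is numerically zero (training inputs
    re-queried), the draw collapses to the mean exactly.
    """
    cv = chol_lower(V)
    JtVinv_resid = J.T @ chol_solve(cv, Y - F @ theta)
    mean = F_new @ theta + JtVinv_resid
    row_cov = symmetrize(V_new - inv_quad(cv, J))
    if float(np.max(np.abs(row_cov), initial=0.0)) <= _DEGENERATE_TOL:
        draw = mean.copy()
        row_cov = np.zeros_like(row_cov)
    else:
        try:
            cr = chol_lower(row_cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "augmented kernel matrix is not positive definite; "
                "check the correlation function"
            ) from exc
        z = rng.standard_normal(mean.shape)
        draw = mean + cr @ z @ chol_col.T
    if return_moments:
        return draw, mean, row_cov
    return draw


def predictive_hyper_t_moments(
    F_new: np.ndarray,
    J: np.ndarray,
    V_new: np.ndarray,
    h_t: np.ndarray,
    H_t: np.ndarray,
    n_T: float,
    D_T: np.ndarray,
    Y: np.ndarray,
    F: np.ndarray,
    V: np.ndarray,
):
    """Parameters (location, row-scale, dof, column-scale) of the hyper-T
    posterior predictive at new inputs:

    location = F_new h_t + J^T V^{-1}(Y - F h_t)
    scale    = F_new H_t F_new^T + V_new - (F H_t F_new^T + J)^T
               (F H_t F^T + V)^{-1} (F H_t F_new^T + J)
    """
    cv = chol_lower(V)
    location = F_new @ h_t + J.T @ chol_solve(cv, Y - F @ h_t)
    cross = F @ H_t @ F_new.T + J
    qmat = symmetrize(F @ H_t @ F.T + V)
    cq = chol_lower(qmat)
    scale = symmetrize(F_new @ H_t @ F_new.T + V_new - inv_quad(cq, cross))
    return location, scale, n_T, D_T
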