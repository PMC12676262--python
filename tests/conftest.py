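"""Shared fixtures and independent oracles.

The batch-conjugacy oracle builds the joint matrix-normal distribution of all
states and observations by propagating innovation coefficients, then
conditions directly — no filtering code is reused.
"""

from __future__ import annotations

import numpy as np
import pytest

from dynemu.ffbs import DLMSpec
from dynemu.matdist import MNIWState


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_spd(rng, n: int, scale: float = 1.0) -> np.ndarray:
    a = rng.standard_normal((n, n + 2))
    return scale * (a @ a.T / (n + 2) + 0.5 * np.eye(n))


def random_mniw_dlm(rng, p=2, N=2, S=2, T=3):
    """A random, well-conditioned MNIW DLM instance plus simulated data."""
    prior = MNIWState(
        m=rng.standard_normal((p, S)),
        M=random_spd(rng, p),
        n=S + 3.0,
        D=random_spd(rng, S),
    )
    F = [rng.standard_normal((N, p)) for _ in range(T)]
    G = [np.eye(p) + 0.1 * rng.standard_normal((p, p)) for _ in range(T)]
    V = [random_spd(rng, N) for _ in range(T)]
    W = [random_spd(rng, p) for _ in range(T)]
    spec = DLMSpec(F=F, G=G, V=V, W=W, prior=prior, T=T)
    Y = [rng.standard_normal((N, S)) for _ in range(T)]
    return Y, spec


class BatchOracle:
    """Joint-Gaussian conditioning oracle for the MNIW DLM.

    Stacks [Theta_0; ...; Theta_T; Y_1; ...; Y_T] as one matrix-normal with
    shared column covariance Sigma, built from the innovation row covariances
    blockdiag(M0, W_1..W_T, V_1..V_T) and the linear propagation maps.
    """

    def __init__(self, Y, spec: DLMSpec):
        p = spec.prior.shape[0]
        T = spec.T
        Ns = [spec.F[t].shape[0] for t in range(T)]
        n_innov = p * (T + 1) + sum(Ns)
        R = np.zeros((n_innov, n_innov))
        R[:p, :p] = spec.prior.M
        off = p
        for t in range(T):
            R[off:off + p, off:off + p] = spec.W[t]
            off += p
        for t in range(T):
            R[off:off + Ns[t], off:off + Ns[t]] = spec.V[t]
            off += Ns[t]

        # coefficient rows: each stacked row = coeff @ innovations + mean row
        theta_coeff = [None] * (T + 1)
        theta_mean = [None] * (T + 1)
        c0 = np.zeros((p, n_innov))
        c0[:, :p] = np.eye(p)
        theta_coeff[0] = c0
        theta_mean[0] = spec.prior.m.copy()
        for t in range(1, T + 1):
            c = spec.G[t - 1] @ theta_coeff[t - 1]
            c[:, p * t:p * (t + 1)] += np.eye(p)
            theta_coeff[t] = c
            theta_mean[t] = spec.G[t - 1] @ theta_mean[t - 1]
        y_coeff, y_mean = [], []
        off = p * (T + 1)
        for t in range(1, T + 1):
            c = spec.F[t - 1] @ theta_coeff[t]
            c[:, off:off + Ns[t - 1]] += np.eye(Ns[t - 1])
            off += Ns[t - 1]
            y_coeff.append(c)
            y_mean.append(spec.F[t - 1] @ theta_mean[t])

        A_y = np.vstack(y_coeff)
        self.K_yy = A_y @ R @ A_y.T
        self.mu_y = np.vstack(y_mean)
        self.y_obs = np.vstack(Y)
        self.R = R
        self.A_y = A_y
        self.theta_coeff = theta_coeff
        self.theta_mean = theta_mean
        self.spec = spec
        self._Kyy_inv = np.linalg.inv(self.K_yy)

    def sigma_posterior(self):
        """(n, D) of the inverse-Wishart posterior of Sigma."""
        resid = self.y_obs - self.mu_y
        n = self.spec.prior.n + self.y_obs.shape[0]
        D = self.spec.prior.D + resid.T @ self._Kyy_inv @ resid
        return n, D

    def theta_conditional(self, t: int):
        """(mean, row-cov) of Theta_t | Y_{1:T}, Sigma (row-cov is Sigma-free)."""
        A_t = self.theta_coeff[t]
        K_ty = A_t @ self.R @ self.A_y.T
        K_tt = A_t @ self.R @ A_t.T
        gain = K_ty @ self._Kyy_inv
        mean = self.theta_mean[t] + gain @ (self.y_obs - self.mu_y)
        cov = K_tt - gain @ K_ty.T
        return mean, cov

    def pairwise_conditional(self, t: int):
        """Conditional of Theta_t given Theta_{t+1} and Y_{1:t}: (gain, cov).

        Used to validate the lag-1 structure of joint backward draws:
        E[Theta_t | Theta_{t+1}, Y_{1:t}] = mean_t + gain (Theta_{t+1} - mean_{t+1})
        under the *filtered* (not smoothed) information set.
        """
        # restrict to observations up to time t
        p = self.spec.prior.shape[0]
        Ns = [self.spec.F[u].shape[0] for u in range(self.spec.T)]
        rows = sum(Ns[:t])
        A_y = self.A_y[:rows]
        K_yy = A_y @ self.R @ A_y.T
        Kinv = np.linalg.inv(K_yy) if rows else np.zeros((0, 0))
        mu_y = self.mu_y[:rows]

        def cond(a_coeff, mean):
            K_ay = a_coeff @ self.R @ A_y.T
            gain = K_ay @ Kinv if rows else np.zeros((a_coeff.shape[0], 0))
            return mean, gain, a_coeff @ self.R @ a_coeff.T - gain @ K_ay.T

        m_t, g_t, C_tt = cond(self.theta_coeff[t], self.theta_mean[t])
        m_n, g_n, C_nn = cond(self.theta_coeff[t + 1], self.theta_mean[t + 1])
        C_tn = (
            self.theta_coeff[t] @ self.R @ self.theta_coeff[t + 1].T
            - g_t @ (A_y @ self.R @ self.theta_coeff[t + 1].T)
        )
        gain = C_tn @ np.linalg.inv(C_nn)
        cov = C_tt - gain @ C_tn.T
        return gain, cov
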