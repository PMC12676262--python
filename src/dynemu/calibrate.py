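"""Modularized melding of field data with a trained emulator.

Gibbs updates for the observation variances tau^2_{1:T} and the latent
emulator values y_{1:T}(eta), an exact FFBS update for the dynamic spatial
bias u_{0:T}, and a Metropolis random walk for the mechanistic parameters
(and optionally the bias correlation range rho) on a transformed scale.

Each MCMC iteration conditions on one stored emulation draw (cycled), so no
additional emulation is ever run (Bayesian modularization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import expit, logit

from ._linalg import chol_logdet, chol_lower, chol_solve, symmetrize
from .emulator import EmulatorFit, build_ar_design, sq_exp_corr
from .mech_sim import exp_corr

__all__ = [
    "CalibConfig",
    "CalibState",
    "CalibBundle",
    "make_bundle",
    "emulator_conditional",
    "tau2_gibbs",
    "y_gibbs",
    "bias_ffbs",
    "transform_phi",
    "inverse_transform_phi",
    "log_jacobian",
    "log_target_phi",
    "metropolis_step",
    "run_calibration",
]

_KAPPA_TOL = 1e-12


# ---------------------------------------------------------------------------
# configuration and state
# ---------------------------------------------------------------------------

@dataclass
class CalibConfig:
    """Priors, hyperparameters and sampler settings for calibration.

    ``priors`` holds one ("lognormal", mu, sigma) or ("uniform", a, b) tuple
    per mechanistic parameter.  ``rho`` is the bias-correlation range (fixed
    unless ``fix_rho=False``, in which case ``rho_prior`` must be given and
    rho is appended to the Metropolis block).
    """

    priors: Sequence[tuple]
    coords: np.ndarray
    rho: float = 1.5
    fix_rho: bool = True
    rho_prior: tuple | None = None
    b: float | np.ndarray = 1.0
    n0z: float = 2.0
    d0z: float = 1.0
    m0z: float | np.ndarray = 0.0
    M0z: np.ndarray | None = None
    tau0sq: float = 1.0
    step_scale: float = 0.2
    adapt_iters: int | None = None
    target_accept: tuple = (0.2, 0.4)
    bias_modularized: bool = False

    def U(self, rho: float | None = None) -> np.ndarray:
        return exp_corr(self.coords, self.rho if rho is None else rho)


@dataclass
class CalibState:
    """One MCMC state: (eta, rho, tau^2_{1:T}, u_{0:T}, y_{1:T})."""

    eta: np.ndarray
    rho: float
    tau2: np.ndarray
    u: np.ndarray
    y: np.ndarray


@dataclass
class CalibBundle:
    """Stored emulation draws restricted to the field locations.

    Built once from a trained :class:`~dynemu.emulator.EmulatorFit`; the
    calibration sampler never re-runs emulation.  ``theta_site`` is stacked
    (L, T+1, p, S~), ``resid_site`` holds the precomputed training residuals
    Y_t(S~) - F_t Theta_t(S~) as (L, T, N, S~), and ``sigma_site`` is
    (L, S~, S~).
    """

    inputs: np.ndarray
    beta: np.ndarray
    chol_V: np.ndarray
    F: list                # per-time N x p training designs
    Y_site: list           # per-time (1..T) N x S~ training outputs at field sites
    theta_site: np.ndarray
    resid_site: np.ndarray
    sigma_site: np.ndarray
    ar_order: int
    y0_row: np.ndarray      # initial output row shared by the AR design, (S~,)
    T: int

    @property
    def L(self) -> int:
        return self.theta_site.shape[0]

    @property
    def n_sites(self) -> int:
        return self.y0_row.size


def make_bundle(fit: EmulatorFit, site_idx: Sequence[int]) -> CalibBundle:
    """Restrict a trained emulator's draws to the field-data locations.

    ``site_idx`` indexes the emulation columns; under MNIW emulation the field
    locations must be a subset of the training locations (pass the MNIG path
    with a spatial R to emulate at off-design locations).
    """
    sidx = np.asarray(site_idx, dtype=int)
    s_train = fit.Y[0].shape[1]
    if np.any(sidx < 0) or np.any(sidx >= s_train):
        raise ValueError(
            "field locations outside the emulation set: the unstructured "
            "covariance path requires field sites to be a subset of the "
            "training sites (use the sigma^2 R structure otherwise)"
        )
    res = fit.result
    ix = np.ix_(sidx, sidx)
    theta_site = np.asarray(
        [[th[:, sidx] for th in res.thetas[l]] for l in range(res.L)]
    )  # (L, T+1, p, S~)
    if fit.structure == "identity":
        sigma_site = np.broadcast_to(
            np.eye(sidx.size), (res.L, sidx.size, sidx.size)
        ).copy()
    elif res.sigma2 is not None:
        sigma_site = res.sigma2[:, None, None] * fit.spec.prior.R[ix][None]
    else:
        sigma_site = res.sigmas[:, sidx, :][:, :, sidx]
    F_stack = np.asarray([fit.spec.F[t] for t in range(fit.T)])  # (T, N, p)
    Y_stack = np.asarray([fit.Y[t][:, sidx] for t in range(1, fit.T + 1)])
    resid_site = Y_stack[None] - np.einsum(
        "tnp,ltps->ltns", F_stack, theta_site[:, 1:], optimize=True
    )
    y0 = fit.Y[0][0, sidx]
    if not np.allclose(fit.Y[0], fit.Y[0][0], atol=1e-10):
        raise ValueError(
            "calibration with AR designs assumes a shared initial output row "
            "across training inputs (a common mechanistic initial condition)"
        )
    if sidx.size != s_train:
        # F~_t(eta) regresses on the full lagged output row, which is only
        # available when every emulation column is tracked by the sampler
        raise ValueError(
            "AR emulator designs need the sampled field values at every "
            "training location; supply site_idx covering all columns"
        )
    return CalibBundle(
        inputs=fit.inputs, beta=fit.beta, chol_V=fit.chol_V,
        F=[fit.spec.F[t] for t in range(fit.T)],
        Y_site=[fit.Y[t][:, sidx] for t in range(1, fit.T + 1)],
        theta_site=theta_site, resid_site=resid_site, sigma_site=sigma_site,
        ar_order=fit.ar_order, y0_row=y0, T=fit.T,
    )


# ---------------------------------------------------------------------------
# emulator conditional at a proposed eta
# ---------------------------------------------------------------------------

def emulator_conditional(
    eta: np.ndarray,
    draw_idx: int,
    bundle: CalibBundle,
    y_state: np.ndarray,
):
    """Conditional predictive moments of y_t(eta) given one emulation draw.

    mu_t(eta)^T = F~_t(eta) Theta_t(S~) + J(eta)^T V^{-1} (Y_t(S~) - F_t Theta_t(S~))
    Sigma_t(eta) = (1 - J(eta)^T V^{-1} J(eta)) Sigma(S~)

    The AR design row F~_t(eta) is built from the current sampled values
    ``y_state`` (rows t = 1..T; the known initial row seeds lag 0).  Returns
    (mu: (T, S~), kappa: scalar in [0, 1], Sigma(S~)).
    """
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    J = sq_exp_corr(bundle.inputs, eta[None, :], bundle.beta)  # (N, 1)
    w = chol_solve(bundle.chol_V, J)[:, 0]  # V^{-1} J
    kappa = max(float(1.0 - J[:, 0] @ w), 0.0)
    hist = [bundle.y0_row[None, :]] + [y_state[t][None, :] for t in range(bundle.T)]
    f_new = np.concatenate(
        [build_ar_design(hist, bundle.ar_order, t) for t in range(1, bundle.T + 1)]
    )  # (T, p)
    thetas = bundle.theta_site[draw_idx]  # (T+1, p, S~)
    mu = np.einsum("tp,tps->ts", f_new, thetas[1:]) + np.einsum(
        "n,tns->ts", w, bundle.resid_site[draw_idx]
    )
    return mu, kappa, bundle.sigma_site[draw_idx]


# ---------------------------------------------------------------------------
# Gibbs blocks
# ---------------------------------------------------------------------------

def tau2_gibbs(
    u: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    chol_U: np.ndarray,
    config: CalibConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw tau^2_t ~ IG(b_t n0 + S~, b_t d0 + (Q1 + Q2)/2) for every season."""
    T, s_obs = z.shape
    b = np.broadcast_to(np.asarray(config.b, dtype=float), (T,))
    du = np.diff(u, axis=0)  # (T, S~)
    q1 = np.sum(
        solve_triangular(chol_U, du.T, lower=True, check_finite=False) ** 2, axis=0
    )
    r = z - y - u[1:]
    q2 = np.sum(r * r, axis=1)
    shape = b * config.n0z + s_obs
    rate = b * config.d0z + 0.5 * (q1 + q2)
    if not np.all(np.isfinite(rate)):
        raise FloatingPointError(
            f"non-finite tau^2 rate at t={int(np.flatnonzero(~np.isfinite(rate))[0]) + 1}"
        )
    return 1.0 / rng.gamma(shape, 1.0 / rate)


def y_gibbs(
    mu: np.ndarray,
    kappa: float,
    sigma_site: np.ndarray,
    tau2: np.ndarray,
    z: np.ndarray,
    u: np.ndarray,
    rng: np.random.Generator,
    return_moments: bool = False,
):
    """Draw y_t(eta) ~ N(B_t b_t, B_t), B_t^{-1} = Sigma~_t^{-1} + tau_t^{-2} I.

    When the emulator conditional is degenerate (eta at a training input,
    kappa ~ 0) the draw collapses to mu_t exactly.
    """
    T, s_obs = mu.shape
    sig = kappa * sigma_site
    degenerate = kappa <= _KAPPA_TOL or float(np.max(np.abs(sig))) <= _KAPPA_TOL
    if degenerate:
        y = mu.copy()
        if return_moments:
            return y, mu.copy(), np.zeros((T, s_obs, s_obs))
        return y
    eye = np.eye(s_obs)
    stack = sig[None] + tau2[:, None, None] * eye[None]  # (T, S~, S~)
    gains = np.linalg.solve(stack, np.broadcast_to(sig, (T, s_obs, s_obs)))
    means = mu + np.einsum("tsr,tr->ts", np.transpose(gains, (0, 2, 1)),
                           z - u[1:] - mu)
    covs = sig[None] - sig[None] @ gains
    covs = 0.5 * (covs + np.transpose(covs, (0, 2, 1)))
    chols = np.linalg.cholesky(
        covs + 1e-14 * np.trace(sig) * eye[None]
    )
    y = means + np.einsum("tsr,tr->ts", chols, rng.standard_normal((T, s_obs)))
    if return_moments:
        return y, means, covs
    return y


def bias_ffbs(
    z: np.ndarray,
    y: np.ndarray,
    tau2: np.ndarray,
    U: np.ndarray,
    config: CalibConfig,
    rng: np.random.Generator,
    return_moments: bool = False,
):
    """One joint draw of the dynamic bias path u_{0:T} from its full conditional.

    Forward filter on the random-walk bias model

        A~_t = tau^2_{t-1} M_{t-1} + tau^2_t U;  Q~_t = A~_t + tau^2_t I
        m_t  = m_{t-1} + A~_t Q~_t^{-1} (z_t - y_t - m_{t-1})
        M_t  = tau_t^{-2} (A~_t - A~_t Q~_t^{-1} A~_t)

    then a backward pass sampling u_t | u_{t+1} from the exact sequential
    conditional; the marginal smoothed moments (h~_t, H~_t) of the printed
    recursion are returned on request.
    """
    T, s_obs = z.shape
    m = [np.broadcast_to(np.asarray(config.m0z, dtype=float), (s_obs,)).copy()]
    M0 = np.eye(s_obs) if config.M0z is None else np.asarray(config.M0z, dtype=float)
    M = [M0]
    tau_all = np.concatenate([[config.tau0sq], tau2])  # tau_0^2 first
    A_list = [None]
    eye = np.eye(s_obs)
    for t in range(1, T + 1):
        A = symmetrize(tau_all[t - 1] * M[t - 1] + tau_all[t] * U)
        Q = symmetrize(A + tau_all[t] * eye)
        cq = chol_lower(Q)
        gain = chol_solve(cq, A)  # Q^{-1} A
        resid = z[t - 1] - y[t - 1] - m[t - 1]
        m.append(m[t - 1] + gain.T @ resid)
        M.append(symmetrize((A - A @ gain) / tau_all[t]))
        A_list.append(A)

    u = np.empty((T + 1, s_obs))
    h = [None] * (T + 1)
    H = [None] * (T + 1)
    h[T] = m[T]
    H[T] = symmetrize(tau_all[T] * M[T])
    cov_T = H[T]
    u[T] = h[T] + chol_lower(cov_T) @ rng.standard_normal(s_obs)
    for t in range(T - 1, -1, -1):
        var_t = tau_all[t] * M[t]  # filtered covariance of u_t
        ca = chol_lower(A_list[t + 1])
        gain = chol_solve(ca, var_t).T  # var_t A_{t+1}^{-1}
        cond_mean = m[t] + gain @ (u[t + 1] - m[t])
        cond_cov = symmetrize(var_t - gain @ var_t)
        u[t] = cond_mean + _safe_chol(cond_cov) @ rng.standard_normal(s_obs)
        h[t] = m[t] + gain @ (h[t + 1] - m[t])
        H[t] = symmetrize(var_t - gain @ (A_list[t + 1] - H[t + 1]) @ gain.T)
    if return_moments:
        return u, h, H
    return u


def _safe_chol(cov: np.ndarray) -> np.ndarray:
    if float(np.max(np.abs(cov), initial=0.0)) <= 1e-14:
        return np.zeros_like(cov)
    return chol_lower(cov)


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

def _phi_priors(config: CalibConfig) -> list[tuple]:
    priors = list(config.priors)
    if not config.fix_rho:
        if config.rho_prior is None:
            raise ValueError("sampling rho requires rho_prior")
        priors = [config.rho_prior] + priors
    return priors


def transform_phi(phi: np.ndarray, priors: Sequence[tuple]) -> np.ndarray:
    """Map positive/bounded parameters to the real line, one prior per entry."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    out = np.empty_like(phi)
    for i, spec in enumerate(priors):
        kind = spec[0]
        if kind == "lognormal":
            mu, sigma = spec[1], spec[2]
            if phi[i] <= 0:
                raise ValueError(f"component {i} must be positive")
            out[i] = (np.log(phi[i]) - mu) / sigma
        elif kind == "uniform":
            a, b = spec[1], spec[2]
            if not a < phi[i] < b:
                raise ValueError(f"component {i} outside ({a}, {b})")
            out[i] = logit((phi[i] - a) / (b - a))
        else:
            raise ValueError(f"unknown prior kind {kind!r}")
    return out


def inverse_transform_phi(psi: np.ndarray, priors: Sequence[tuple]) -> np.ndarray:
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    out = np.empty_like(psi)
    for i, spec in enumerate(priors):
        kind = spec[0]
        if kind == "lognormal":
            out[i] = np.exp(spec[1] + spec[2] * psi[i])
        else:
            a, b = spec[1], spec[2]
            out[i] = a + (b - a) * expit(psi[i])
    return out


def log_jacobian(phi: np.ndarray, priors: Sequence[tuple]) -> float:
    """log |dg/dphi|: lognormal gives prod (phi_i sigma_i)^{-1}; uniform gives
    prod [(phi_i - a_i)^{-1} + (b_i - phi_i)^{-1}]."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    total = 0.0
    for i, spec in enumerate(priors):
        if spec[0] == "lognormal":
            total += -np.log(phi[i] * spec[2])
        else:
            a, b = spec[1], spec[2]
            total += np.log(1.0 / (phi[i] - a) + 1.0 / (b - phi[i]))
    return float(total)


# ---------------------------------------------------------------------------
# Metropolis block
# ---------------------------------------------------------------------------

def log_target_phi(
    psi: np.ndarray,
    draw_idx: int,
    bundle: CalibBundle,
    state: CalibState,
    z: np.ndarray,
    config: CalibConfig,
) -> float:
    """Log full-conditional of the transformed parameter block.

    Sums the Gaussian full-conditional terms for y_t at (B_t b_t, B_t), the
    observation terms for z, the bias-innovation terms with U(rho), and the
    standard-normal prior on the transformed scale (the original-scale prior
    density minus the log-Jacobian).
    """
    priors = _phi_priors(config)
    phi = inverse_transform_phi(psi, priors)
    if config.fix_rho:
        rho, eta = config.rho, phi
    else:
        rho, eta = float(phi[0]), phi[1:]
    T, s_obs = z.shape
    mu, kappa, sig_site = emulator_conditional(eta, draw_idx, bundle, state.y)
    _, means, covs = y_gibbs(
        mu, kappa, sig_site, state.tau2, z, state.u, np.random.default_rng(0),
        return_moments=True,
    )
    total = 0.0
    if kappa <= _KAPPA_TOL:
        # degenerate emulator conditional: y pinned at mu
        if not np.allclose(state.y, mu, atol=1e-8):
            return -np.inf
    else:
        chols = np.linalg.cholesky(covs)
        dev = np.linalg.solve(
            chols, (state.y - means)[:, :, None]
        )[:, :, 0]
        logdets = 2.0 * np.sum(np.log(np.diagonal(chols, axis1=1, axis2=2)))
        total += -0.5 * (
            T * s_obs * np.log(2.0 * np.pi) + logdets + float(np.sum(dev * dev))
        )
    r = z - state.y - state.u[1:]
    total += -0.5 * float(np.sum(
        s_obs * np.log(2.0 * np.pi * state.tau2)
        + np.sum(r * r, axis=1) / state.tau2
    ))
    U = config.U(rho)
    cu = chol_lower(U)
    du = np.diff(state.u, axis=0)
    wv = solve_triangular(cu, du.T, lower=True, check_finite=False)
    total += -0.5 * float(np.sum(
        s_obs * np.log(2.0 * np.pi * state.tau2)
        + chol_logdet(cu)
        + np.sum(wv * wv, axis=0) / state.tau2
    ))
    total += -0.5 * float(psi @ psi) - 0.5 * psi.size * np.log(2.0 * np.pi)
    return float(total)


def metropolis_step(
    psi: np.ndarray,
    log_target,
    chol_upsilon: np.ndarray,
    rng: np.random.Generator,
    current_lp: float | None = None,
):
    """One Gaussian random-walk Metropolis step on the transformed scale."""
    if current_lp is None:
        current_lp = log_target(psi)
    prop = psi + chol_upsilon @ rng.standard_normal(psi.size)
    lp_prop = log_target(prop)
    if np.log(rng.uniform()) < lp_prop - current_lp:
        return prop, True, lp_prop
    return psi, False, current_lp


# ---------------------------------------------------------------------------
# full sampler
# ---------------------------------------------------------------------------

def run_calibration(
    z: np.ndarray,
    bundle: CalibBundle,
    config: CalibConfig,
    iters: int,
    rng: np.random.Generator,
) -> dict:
    """Modularized calibration sampler (tau^2 -> u -> phi -> y per iteration).

    Each iteration conditions on one stored emulation draw, cycling through
    the bundle.  Returns full traces and the realized acceptance rate.
    """
    z = np.asarray(z, dtype=float)
    T, s_obs = z.shape
    if T != bundle.T or s_obs != bundle.n_sites:
        raise ValueError(f"field data must be {bundle.T} x {bundle.n_sites}")
    priors = _phi_priors(config)
    d_phi = len(priors)
    d_eta = len(config.priors)

    # initial state: prior-median eta, unit variances, zero bias
    psi = np.zeros(d_phi)
    phi0 = inverse_transform_phi(psi, priors)
    eta = phi0[-d_eta:]
    rho = config.rho if config.fix_rho else float(phi0[0])
    tau2 = np.ones(T)
    u = np.zeros((T + 1, s_obs))
    mu0, _, _ = emulator_conditional(eta, 0, bundle, np.zeros((T, s_obs)))
    mu0, _, _ = emulator_conditional(eta, 0, bundle, mu0)  # refresh AR lags
    state = CalibState(eta=eta, rho=rho, tau2=tau2, u=u, y=mu0.copy())

    U_fixed = config.U() if config.fix_rho else None
    chol_U_fixed = chol_lower(U_fixed) if U_fixed is not None else None

    adapt = config.adapt_iters
    if adapt is None:
        adapt = min(1000, iters // 4)
    step = config.step_scale
    chol_ups = step * np.eye(d_phi)

    traces = {
        "eta": np.empty((iters, d_eta)),
        "rho": np.empty(iters),
        "tau2": np.empty((iters, T)),
        "u": np.empty((iters, T + 1, s_obs)),
        "y": np.empty((iters, T, s_obs)),
        "accept": np.zeros(iters, dtype=bool),
        "logpost": np.empty(iters),
    }
    window_acc = 0
    window_n = 0
    lp_cache = None
    for l in range(iters):
        draw_idx = l % bundle.L
        U_now = U_fixed if config.fix_rho else config.U(state.rho)
        chol_U = chol_U_fixed if config.fix_rho else chol_lower(U_now)

        state.tau2 = tau2_gibbs(state.u, state.y, z, chol_U, config, rng)
        if not config.bias_modularized:
            state.u = bias_ffbs(z, state.y, state.tau2, U_now, config, rng)

        def _target(p):
            return log_target_phi(p, draw_idx, bundle, state, z, config)

        psi, accepted, lp_cache = metropolis_step(psi, _target, chol_ups, rng)
        phi = inverse_transform_phi(psi, priors)
        if config.fix_rho:
            state.eta = phi
        else:
            state.rho, state.eta = float(phi[0]), phi[1:]
        mu, kappa, sig_site = emulator_conditional(
            state.eta, draw_idx, bundle, state.y
        )
        state.y = y_gibbs(mu, kappa, sig_site, state.tau2, z, state.u, rng)

        traces["eta"][l] = state.eta
        traces["rho"][l] = state.rho
        traces["tau2"][l] = state.tau2
        traces["u"][l] = state.u
        traces["y"][l] = state.y
        traces["accept"][l] = accepted
        traces["logpost"][l] = lp_cache
        lp_cache = None  # state changed in the Gibbs blocks; recompute next time

        window_acc += accepted
        window_n += 1
        if l < adapt and window_n == 50:
            rate = window_acc / window_n
            lo, hi = config.target_accept
            if rate < lo:
                step *= 0.7
            elif rate > hi:
                step *= 1.4
            chol_ups = step * np.eye(d_phi)
            window_acc = window_n = 0

    if config.bias_modularized:
        # post-hoc bias draws conditioning on the sampled parameters
        for l in range(iters):
            U_now = U_fixed if config.fix_rho else config.U(traces["rho"][l])
            traces["u"][l] = bias_ffbs(
                z, traces["y"][l], traces["tau2"][l], U_now, config, rng
            )
    traces["accept_rate"] = float(np.mean(traces["accept"]))
    traces["step_scale"] = step
    traces["burn_in"] = adapt
    return traces
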