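"""Built-in mechanistic systems and synthetic-data generators.

Lotka-Volterra predator-prey ODE, SIR reaction-diffusion PDE on a regular
grid (method of lines, RK4, zero-flux boundaries), deterministic network
activation diffusion, Latin-hypercube input designs, and noisy field-data
generation with a dynamic spatial bias process.

All simulators are deterministic given their parameters; randomness enters
only through design generation and field noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.spatial.distance import cdist
from scipy.stats import norm, qmc

from ._linalg import chol_lower

__all__ = [
    "LVParams",
    "SIRPDEParams",
    "NetworkModel",
    "lv_solve",
    "lv_training_tensor",
    "sir_pde_solve",
    "sir_training_tensor",
    "network_diffusion_run",
    "lhs_design",
    "exp_corr",
    "make_field_data",
]


@dataclass(frozen=True)
class LVParams:
    """Lotka-Volterra rates: prey growth, predation loss, predator death, predation gain."""

    eta1: float
    eta2: float
    eta3: float
    eta4: float

    def __post_init__(self) -> None:
        if min(self.eta1, self.eta2, self.eta3, self.eta4) <= 0:
            raise ValueError("all Lotka-Volterra rates must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.eta1, self.eta2, self.eta3, self.eta4])


def lv_solve(
    params: LVParams,
    u0: float,
    v0: float,
    times: np.ndarray,
    rtol: float = 1e-9,
    atol: float = 1e-10,
) -> np.ndarray:
    """Solve du/dt = eta1 u - eta2 u v, dv/dt = -eta3 v + eta4 u v.

    Returns a (len(times), 2) array of (prey, predator) populations.
    """
    if u0 <= 0 or v0 <= 0:
        raise ValueError("initial populations must be positive")
    times = np.asarray(times, dtype=float)
    e1, e2, e3, e4 = params.array

    def rhs(_t, y):
        u, v = y
        return (e1 * u - e2 * u * v, -e3 * v + e4 * u * v)

    sol = solve_ivp(
        rhs, (times[0], times[-1]), (u0, v0), t_eval=times,
        rtol=rtol, atol=atol, method="RK45", dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"Lotka-Volterra solver failed: {sol.message}")
    return sol.y.T


def lv_training_tensor(
    etas: np.ndarray, u0: float, v0: float, T: int, log: bool = True
) -> np.ndarray:
    """Solve the predator-prey system at each input row; stack to (T+1, N, 2).

    With ``log`` the outputs are log populations (the emulation scale).
    """
    etas = np.atleast_2d(np.asarray(etas, dtype=float))
    times = np.arange(T + 1, dtype=float)
    out = np.empty((T + 1, etas.shape[0], 2))
    for i, row in enumerate(etas):
        traj = lv_solve(LVParams(*row), u0, v0, times)
        out[:, i, :] = np.log(traj) if log else traj
    return out


# ---------------------------------------------------------------------------
# SIR reaction-diffusion PDE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SIRPDEParams:
    """Transmission/recovery rates, per-compartment diffusion, grid and seeding."""

    eta1: float
    eta2: float
    alpha1: float
    alpha2: float
    alpha3: float
    nx: int
    ny: int
    N_pop: float = 1.0
    seeds: tuple = ()  # ((ix, iy, initial_infected), ...)

    def __post_init__(self) -> None:
        if min(self.eta1, self.eta2, self.alpha1, self.alpha2, self.alpha3) < 0:
            raise ValueError("rates and diffusion coefficients must be nonnegative")
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid must be at least 2x2")


def _laplacian(f: np.ndarray) -> np.ndarray:
    """5-point Laplacian with zero-flux (reflecting) boundaries, unit spacing."""
    up = np.vstack([f[:1], f[:-1]])
    down = np.vstack([f[1:], f[-1:]])
    left = np.hstack([f[:, :1], f[:, :-1]])
    right = np.hstack([f[:, 1:], f[:, -1:]])
    return up + down + left + right - 4.0 * f


def sir_pde_solve(
    params: SIRPDEParams, T: int, dt: float | None = None
) -> dict[str, np.ndarray]:
    """Method-of-lines RK4 integration of the diffusive SIR system.

    dS/dt = -eta1 S I / N + alpha1 lap(S)
    dI/dt =  eta1 S I / N - eta2 I + alpha2 lap(I)
    dR/dt =  eta2 I + alpha3 lap(R)

    Returns fields of shape (T+1, nx, ny) for "S", "I", "R" at integer times.
    """
    nx, ny = params.nx, params.ny
    S = np.full((nx, ny), params.N_pop, dtype=float)
    I = np.zeros((nx, ny))
    for ix, iy, i0 in params.seeds:
        I[ix, iy] = i0
        S[ix, iy] = max(params.N_pop - i0, 0.0)
    R = np.zeros((nx, ny))
    if dt is None:
        a_max = max(params.alpha1, params.alpha2, params.alpha3)
        react = params.eta1 + params.eta2
        dt = min(0.2, 0.5 / (4.0 * a_max + react + 1e-9))
    n_sub = int(np.ceil(1.0 / dt))
    h = 1.0 / n_sub
    e1, e2 = params.eta1, params.eta2
    a1, a2, a3 = params.alpha1, params.alpha2, params.alpha3
    Npop = params.N_pop

    def rhs(s, i, r):
        inf = e1 * s * i / Npop
        return (
            -inf + a1 * _laplacian(s),
            inf - e2 * i + a2 * _laplacian(i),
            e2 * i + a3 * _laplacian(r),
        )

    outS = np.empty((T + 1, nx, ny))
    outI = np.empty((T + 1, nx, ny))
    outR = np.empty((T + 1, nx, ny))
    outS[0], outI[0], outR[0] = S, I, R
    for t in range(1, T + 1):
        for _ in range(n_sub):
            k1 = rhs(S, I, R)
            k2 = rhs(S + 0.5 * h * k1[0], I + 0.5 * h * k1[1], R + 0.5 * h * k1[2])
            k3 = rhs(S + 0.5 * h * k2[0], I + 0.5 * h * k2[1], R + 0.5 * h * k2[2])
            k4 = rhs(S + h * k3[0], I + h * k3[1], R + h * k3[2])
            S = S + h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            I = I + h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            R = R + h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if not (np.all(np.isfinite(S)) and np.all(np.isfinite(I)) and np.all(np.isfinite(R))):
            raise RuntimeError(f"PDE integration unstable at t={t}; reduce dt")
        outS[t], outI[t], outR[t] = S, I, R
    return {"S": outS, "I": outI, "R": outR}


def sir_training_tensor(
    inputs: np.ndarray,
    nx: int,
    ny: int,
    T: int,
    seeds,
    N_pop: float = 1.0,
) -> np.ndarray:
    """Infection fields log(I + 1) for each input row, stacked to (T+1, N, nx*ny).

    Input rows are (eta1, eta2, alpha1, alpha2, alpha3).
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    out = np.empty((T + 1, inputs.shape[0], nx * ny))
    for i, row in enumerate(inputs):
        p = SIRPDEParams(*row, nx=nx, ny=ny, N_pop=N_pop, seeds=tuple(seeds))
        fields = sir_pde_solve(p, T)
        out[:, i, :] = np.log1p(fields["I"].reshape(T + 1, -1))
    return out


# ---------------------------------------------------------------------------
# network activation diffusion
# ---------------------------------------------------------------------------

@dataclass
class NetworkModel:
    """Adjacency, retention r (scalar or per node), decay d, seeded activation."""

    adjacency: np.ndarray
    r: float | np.ndarray
    d: float
    activation: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1] or not np.array_equal(A, A.T):
            raise ValueError("adjacency must be square and symmetric")
        n = A.shape[0]
        r = np.broadcast_to(np.asarray(self.r, dtype=float), (n,))
        if np.any(r < 0) or np.any(r > 1) or not (0 <= self.d <= 1):
            raise ValueError("retention and decay must lie in [0, 1]")
        act = np.asarray(self.activation, dtype=float)
        if act.shape != (n,) or np.any(act < 0):
            raise ValueError("activation must be a nonnegative length-n vector")


def network_diffusion_run(model: NetworkModel, T: int) -> np.ndarray:
    """Iterate the reservoir/outflow/inflow rules for T steps.

    reservoir(t, n) = r_n * inflow(t, n)
    outflow(t, n)   = (1 - d)(1 - r_n) * inflow(t, n) / deg(n)
    inflow(t+1, n)  = sum_{i ~ n} outflow(t, i) + reservoir(t, n)

    Activation is reported as inflow; row 0 is the seeded activation.
    Returns a (T+1, n) array.
    """
    A = np.asarray(model.adjacency, dtype=float)
    n = A.shape[0]
    deg = A.sum(axis=1)
    r = np.broadcast_to(np.asarray(model.r, dtype=float), (n,))
    inflow = np.asarray(model.activation, dtype=float).copy()
    if np.any((deg == 0) & (inflow > 0)):
        raise ValueError("isolated node carries activation: degree zero")
    out = np.empty((T + 1, n))
    out[0] = inflow
    for t in range(1, T + 1):
        reservoir = r * inflow
        per_edge = np.zeros(n)
        active = deg > 0
        per_edge[active] = (1.0 - model.d) * (1.0 - r[active]) * inflow[active] / deg[active]
        inflow = A @ per_edge + reservoir
        out[t] = inflow
    return out


# ---------------------------------------------------------------------------
# designs and field data
# ---------------------------------------------------------------------------

def lhs_design(
    n_points: int,
    marginals: Sequence[tuple],
    rng: np.random.Generator,
) -> np.ndarray:
    """Latin-hypercube design mapped through per-dimension marginals.

    ``marginals`` is a sequence of ("lognormal", mu, sigma) or
    ("uniform", a, b) tuples, one per input dimension.
    """
    if n_points < 2:
        raise ValueError("need at least two design points")
    d = len(marginals)
    sampler = qmc.LatinHypercube(d=d, seed=rng)
    u = sampler.random(n_points)
    out = np.empty_like(u)
    for j, spec in enumerate(marginals):
        kind = spec[0]
        if kind == "lognormal":
            mu, sigma = spec[1], spec[2]
            out[:, j] = np.exp(mu + sigma * norm.ppf(u[:, j]))
        elif kind == "uniform":
            a, b = spec[1], spec[2]
            if not a < b:
                raise ValueError(f"uniform bounds must satisfy a < b, got ({a}, {b})")
            out[:, j] = a + (b - a) * u[:, j]
        else:
            raise ValueError(f"unknown marginal kind {kind!r}")
    return out


def exp_corr(coords: np.ndarray, rho: float) -> np.ndarray:
    """Exponential correlation exp(-||s - s'|| / rho) over location coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] == 1 and coords.shape[1] > 1:
        coords = coords.T
    if rho <= 0:
        raise ValueError("correlation range rho must be positive")
    return np.exp(-cdist(coords, coords) / rho)


@dataclass
class FieldData:
    """Synthetic observations plus the ground truth that generated them."""

    z: np.ndarray          # (T, S~)
    y_true: np.ndarray     # (T, S~) noiseless mechanistic output
    u_true: np.ndarray     # (T+1, S~) bias path
    tau2: np.ndarray       # (T,)
    eta_true: np.ndarray = field(default_factory=lambda: np.empty(0))


def make_field_data(
    true_eta: np.ndarray,
    simulator: Callable[[np.ndarray], np.ndarray],
    coords: np.ndarray,
    tau2,
    rng: np.random.Generator,
    rho: float | None = None,
    bias: bool = False,
) -> FieldData:
    """Generate z_t(s) = y_t(eta*, s) + u_t(s) + eps, eps ~ N(0, tau_t^2).

    ``simulator`` maps eta to a (T, S~) output array.  With ``bias`` the
    discrepancy u is a random walk with GP increments N(0, tau_t^2 U(rho));
    otherwise u = 0.  Returns observations and the full ground truth.
    """
    true_eta = np.asarray(true_eta, dtype=float)
    y = np.asarray(simulator(true_eta), dtype=float)
    T, s_obs = y.shape
    tau2 = np.broadcast_to(np.asarray(tau2, dtype=float), (T,)).copy()
    u = np.zeros((T + 1, s_obs))
    if bias:
        if rho is None:
            raise ValueError("bias increments need a correlation range rho")
        cu = chol_lower(exp_corr(coords, rho))
        for t in range(1, T + 1):
            u[t] = u[t - 1] + np.sqrt(tau2[t - 1]) * cu @ rng.standard_normal(s_obs)
    eps = np.sqrt(tau2)[:, None] * rng.standard_normal((T, s_obs))
    z = y + u[1:] + eps
    return FieldData(z=z, y_true=y, u_true=u, tau2=tau2, eta_true=true_eta)
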