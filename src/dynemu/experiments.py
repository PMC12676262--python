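"""Replica harnesses for the built-in demonstration experiments.

Predator-prey emulation and calibration on the annual lynx-hare record,
a scaled reaction-diffusion comparison across covariance structures, and a
synthetic-recovery harness for the calibration sampler.  These drive both
the acceptance checks and the command-line demos.
"""

from __future__ import annotations

import numpy as np

from . import compare as cmp
from .calibrate import CalibConfig, make_bundle, run_calibration
from .datasets import lynx_hare_log_matrix
from .emulator import EmulatorFit, default_beta, sq_exp_corr, train_emulator
from .matdist import MNIGState, MNIWState
from .mech_sim import (
    lhs_design,
    lv_training_tensor,
    make_field_data,
    sir_training_tensor,
)
from .transfer import PartitionSpec, partition_stream, stream_spec, streaming_ffbs

__all__ = [
    "LV_MARGINALS",
    "lv_training_data",
    "lv_emulation_experiment",
    "correlation_interval",
    "lv_calibration_experiment",
    "pde_structure_comparison",
    "lv_recovery_replicate",
]

#: Lognormal input marginals of the predator-prey design (mu, sigma per rate).
LV_MARGINALS = [
    ("lognormal", 0.0, 0.5), ("lognormal", -3.0, 0.5),
    ("lognormal", 0.0, 0.5), ("lognormal", -3.0, 0.5),
]


def lv_training_data(
    rng: np.random.Generator, n_inputs: int = 50, T: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LHS design of rate vectors and the log predator-prey output tensor.

    Trajectories start from the 1900 hare/lynx populations of the bundled
    record; returns (design, tensor, initial log row).
    """
    logs = lynx_hare_log_matrix()
    u0, v0 = np.exp(logs[0])
    design = lhs_design(n_inputs, LV_MARGINALS, rng)
    tensor = lv_training_tensor(design, u0, v0, T, log=True)
    return design, tensor, logs[0]


def lv_emulation_experiment(
    seed: int, n_inputs: int = 50, T: int = 20, draws: int = 20000
) -> EmulatorFit:
    """Train the AR(1) matrix-variate emulator on the predator-prey system."""
    rng = np.random.default_rng(seed)
    design, tensor, _ = lv_training_data(rng, n_inputs, T)
    return train_emulator(tensor, design, L=draws, rng=rng, ar_order=1)


def correlation_interval(fit: EmulatorFit) -> tuple[float, float, np.ndarray]:
    """95% credible interval of the column correlation S12/sqrt(S11 S22)."""
    sig = fit.result.sigmas
    corr = sig[:, 0, 1] / np.sqrt(sig[:, 0, 0] * sig[:, 1, 1])
    lo, hi = np.quantile(corr, [0.025, 0.975])
    return float(lo), float(hi), corr


def lv_calibration_experiment(
    seed: int,
    iters: int = 20000,
    n_inputs: int = 50,
    T: int = 20,
    store_draws: int = 2000,
    z: np.ndarray | None = None,
    rho: float = 1.5,
) -> dict:
    """Modularized calibration of the predator-prey rates.

    Field data default to the annual log populations, 1901-1920.  Returns the
    trace dictionary plus per-parameter medians and 95% intervals.
    """
    rng = np.random.default_rng(seed)
    design, tensor, _ = lv_training_data(rng, n_inputs, T)
    fit = train_emulator(tensor, design, L=store_draws, rng=rng, ar_order=1)
    bundle = make_bundle(fit, [0, 1])
    if z is None:
        z = lynx_hare_log_matrix()[1 : T + 1]
    config = CalibConfig(
        priors=LV_MARGINALS,
        coords=np.array([[0.0], [1.0]]),
        rho=rho,
        fix_rho=True,
    )
    traces = run_calibration(np.asarray(z, dtype=float), bundle, config, iters, rng)
    keep = traces["eta"][traces["burn_in"]:]
    q = np.quantile(keep, [0.5, 0.025, 0.975], axis=0)
    traces["medians"] = q[0]
    traces["ci_low"] = q[1]
    traces["ci_high"] = q[2]
    return traces


# ---------------------------------------------------------------------------
# reaction-diffusion structure comparison (scaled)
# ---------------------------------------------------------------------------

#: Uniform LHS ranges around the demonstration PDE parameter point.
PDE_MARGINALS = [
    ("uniform", 2.0, 5.0),      # transmission
    ("uniform", 0.15, 0.4),     # recovery
    ("uniform", 0.005, 0.02),   # S diffusion
    ("uniform", 0.05, 0.25),    # I diffusion
    ("uniform", 0.05, 0.25),    # R diffusion
]


def pde_structure_comparison(
    seed: int,
    grid: int = 6,
    n_inputs: int = 10,
    T: int = 10,
    draws: int = 200,
    length_scale: float | None = None,
) -> dict:
    """Fit the three column-covariance structures to a diffusive-SIR replica.

    The training field is streamed one grid column per episode (r = N,
    c = grid) with an AR(2) design; returns WAIC and D = G + P per structure.
    The sigma^2 R structure uses a squared-exponential R over the grid-column
    coordinates with length-scale one third of the column extent by default.
    """
    rng = np.random.default_rng(seed)
    design = lhs_design(n_inputs, PDE_MARGINALS, rng)
    seeds = ((grid // 2, grid // 2, 0.01), (0, 0, 0.01))
    tensor = sir_training_tensor(design, grid, grid, T, seeds)
    beta = default_beta(design).beta
    V = sq_exp_corr(design, design, beta)
    S = grid * grid
    part = PartitionSpec(N=n_inputs, S=S, r=n_inputs, c=grid)
    Y = [tensor[t] for t in range(1, T + 1)]
    c = grid
    p = 2 * c
    stream = partition_stream(
        Y, "ar", np.eye(p), V, np.eye(p), part,
        Y0=tensor[0], ar_order=2,
    )
    # within-column squared-exponential spatial correlation for sigma^2 R
    if length_scale is None:
        length_scale = grid / 3.0
    coords = np.arange(c, dtype=float)[:, None]
    R = sq_exp_corr(coords, coords, [1.0 / length_scale**2])
    # symmetric weakly-informative priors: prior mean of the column covariance
    # is s2_hat * I under both learned structures (one-step differences proxy
    # the innovation scale)
    s2_hat = float(np.var(np.diff(tensor, axis=0)))
    out: dict[str, dict] = {}
    for structure in ("mniw", "mnig", "identity"):
        if structure == "mnig":
            prior = MNIGState(m=np.zeros((p, c)), M=np.eye(p),
                              n_shape=2.0, d_rate=s2_hat, R=R)
        else:
            prior = MNIWState(m=np.zeros((p, c)), M=np.eye(p),
                              n=c + 2.0, D=s2_hat * np.eye(c))
        fixed = np.eye(c) if structure == "identity" else None
        res = streaming_ffbs(
            stream, prior, draws, np.random.default_rng(seed + 1), fixed_sigma=fixed
        )
        Ys, spec = stream_spec(stream, prior)
        rep = cmp.waic(res, Ys, spec, structure=structure)
        gpd = cmp.gpd_score(res.smoothed, res.filter_out, Ys, spec, structure=structure)
        out[structure] = {
            "waic": rep.waic, "lppd": rep.lppd_mc,
            "lppd_analytic": rep.lppd_analytic, "p_waic": rep.p_waic,
            "G": gpd.G, "P": gpd.P, "D": gpd.D,
        }
    return out


# ---------------------------------------------------------------------------
# synthetic parameter recovery
# ---------------------------------------------------------------------------

def lv_recovery_replicate(
    fit: EmulatorFit,
    y0_log: np.ndarray,
    eta_true: np.ndarray,
    seed: int,
    iters: int = 2000,
    tau: float = 0.01,
) -> dict:
    """One recovery run: synthesize field data at a known rate vector, then
    check whether the 95% posterior intervals cover it."""
    rng = np.random.default_rng(seed)
    T = fit.T
    u0, v0 = np.exp(np.asarray(y0_log, dtype=float))

    def simulator(eta):
        from .mech_sim import lv_training_tensor as gen

        return gen(eta[None, :], u0, v0, T, log=True)[1:, 0, :]

    data = make_field_data(
        eta_true, simulator, coords=np.array([[0.0], [1.0]]),
        tau2=tau**2, rng=rng, bias=False,
    )
    bundle = make_bundle(fit, [0, 1])
    config = CalibConfig(priors=LV_MARGINALS, coords=np.array([[0.0], [1.0]]),
                         rho=1.5, fix_rho=True)
    traces = run_calibration(data.z, bundle, config, iters, rng)
    keep = traces["eta"][traces["burn_in"]:]
    lo, hi = np.quantile(keep, [0.025, 0.975], axis=0)
    covered = (lo <= eta_true) & (eta_true <= hi)
    return {"covered": covered, "ci": (lo, hi), "z": data.z,
            "median": np.median(keep, axis=0)}
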