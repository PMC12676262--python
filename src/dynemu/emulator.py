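"""Gaussian-process structure over mechanistic inputs.

Builds squared-exponential correlation blocks over input designs, AR
observation matrices from lagged outputs, trains the matrix-variate DLM on a
mechanistic output tensor and emulates trajectories at unseen inputs by
sequential conditional prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from ._linalg import chol_lower
from .ffbs import DLMSpec, FFBSResult, ffbs, predictive_conditional
from .matdist import MNIGState, MNIWState

__all__ = [
    "KernelParams",
    "sq_exp_corr",
    "default_beta",
    "build_ar_design",
    "EmulatorFit",
    "train_emulator",
    "emulate",
]


@dataclass(frozen=True)
class KernelParams:
    """Nonnegative decay vector of the squared-exponential kernel."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if np.any(beta < 0):
            raise ValueError("kernel decay parameters must be nonnegative")
        object.__setattr__(self, "beta", beta)


def sq_exp_corr(X1: np.ndarray, X2: np.ndarray, beta) -> np.ndarray:
    """C(x, x') = exp(-sum_i beta_i (x_i - x'_i)^2)."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("input dimension mismatch")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if np.any(beta < 0):
        raise ValueError("kernel decay parameters must be nonnegative")
    if beta.size == 1:
        beta = np.full(X1.shape[1], float(beta[0]))
    sq = cdist(X1 * np.sqrt(beta), X2 * np.sqrt(beta), metric="sqeuclidean")
    return np.exp(-sq)


def default_beta(
    inputs: np.ndarray,
    rule: Callable[[float], float] | None = None,
) -> KernelParams:
    """Default isotropic decay from the maximum pairwise input distance.

    The default rule sets ``beta = 30.5 * d_max``, a short effective range
    that leaves appreciable correlation only between near-identical inputs
    (interpolation at training inputs is exact for any beta).  Pass ``rule``
    (a function of ``d_max``) to replace it, e.g.
    ``rule=lambda d: 3.0 / (0.5 * d) ** 2`` for a half-range convention.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if inputs.shape[0] < 2:
        raise ValueError("need at least two inputs to set a default decay")
    d_max = float(np.max(cdist(inputs, inputs)))
    if d_max <= 0:
        raise ValueError("all inputs identical: maximum pairwise distance is zero")
    value = 30.5 * d_max if rule is None else float(rule(d_max))
    return KernelParams(beta=np.full(inputs.shape[1], value))


def build_ar_design(
    Y_history: Sequence[np.ndarray], ar_order: int, t: int
) -> np.ndarray:
    """Observation matrix F_t from lagged outputs.

    ``Y_history[j]`` is the output at time j (j = 0..t-1 at least).  AR(1)
    gives ``F_t = Y_{t-1}``; AR(2) concatenates ``[Y_{t-1}, Y_{t-2}]``
    column-wise, padding missing lags with ``Y_0``.
    """
    if ar_order not in (1, 2):
        raise ValueError("ar_order must be 1 or 2")
    if t < 1:
        raise ValueError("AR design defined for t >= 1")
    lags = []
    for lag in range(1, ar_order + 1):
        j = max(t - lag, 0)  # pad with Y_0 below the first available lag
        lags.append(np.asarray(Y_history[j], dtype=float))
    return np.concatenate(lags, axis=1) if ar_order > 1 else lags[0]


@dataclass
class EmulatorFit:
    """A trained dynamic emulator: kernel, design, DLM spec and posterior draws."""

    inputs: np.ndarray
    beta: np.ndarray
    ar_order: int
    Y: list  # length T+1 list of N x S outputs (index 0 = initial state)
    V: np.ndarray
    spec: DLMSpec
    result: FFBSResult
    structure: str = "mniw"
    _chol_V: np.ndarray | None = field(default=None, repr=False)

    @property
    def T(self) -> int:
        return len(self.Y) - 1

    @property
    def chol_V(self) -> np.ndarray:
        if self._chol_V is None:
            self._chol_V = chol_lower(self.V)
        return self._chol_V

    def design_at(self, Y_history: Sequence[np.ndarray], t: int) -> np.ndarray:
        return build_ar_design(Y_history, self.ar_order, t)


def train_emulator(
    tensor: np.ndarray,
    inputs: np.ndarray,
    L: int,
    rng: np.random.Generator,
    ar_order: int = 1,
    beta=None,
    structure: str = "mniw",
    R: np.ndarray | None = None,
    prior: MNIWState | MNIGState | None = None,
) -> EmulatorFit:
    """Fit the matrix-variate DLM to a mechanistic output tensor.

    Parameters
    ----------
    tensor : (T+1, N, S) array of outputs over time, inputs and sites.
    inputs : (N, d) design matrix.
    L : number of joint posterior draws.
    structure : "mniw" (Sigma ~ IW), "mnig" (Sigma = sigma^2 R) or
        "identity" (Sigma = I reference model).
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3:
        raise ValueError("training tensor must be (T+1, N, S)")
    T = tensor.shape[0] - 1
    n_inputs, s_sites = tensor.shape[1], tensor.shape[2]
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if inputs.shape[0] != n_inputs:
        raise ValueError("design matrix rows must match tensor input axis")
    if structure not in ("mniw", "mnig", "identity"):
        raise ValueError(f"unknown structure {structure!r}")
    if beta is None:
        beta = default_beta(inputs).beta
    else:
        beta = KernelParams(beta=np.asarray(beta, dtype=float)).beta
    V = sq_exp_corr(inputs, inputs, beta)
    Y = [tensor[t] for t in range(T + 1)]
    F = [build_ar_design(Y, ar_order, t) for t in range(1, T + 1)]
    p = ar_order * s_sites
    if prior is None:
        if structure == "mnig":
            if R is None:
                R = np.eye(s_sites)
            prior = MNIGState(
                m=np.zeros((p, s_sites)), M=np.eye(p), n_shape=2.0, d_rate=1.0, R=R
            )
        else:
            prior = MNIWState(
                m=np.zeros((p, s_sites)), M=np.eye(p),
                n=s_sites + 2.0, D=np.eye(s_sites),
            )
    spec = DLMSpec(F=F, G=np.eye(p), V=V, W=np.eye(p), prior=prior, T=T)
    fixed_sigma = np.eye(s_sites) if structure == "identity" else None
    result = ffbs(Y[1:], spec, L, rng, fixed_sigma=fixed_sigma)
    return EmulatorFit(
        inputs=inputs, beta=beta, ar_order=ar_order, Y=Y, V=V, spec=spec,
        result=result, structure=structure,
    )


def emulate(
    fit: EmulatorFit,
    new_inputs: np.ndarray,
    new_Y0: np.ndarray,
    rng: np.random.Generator,
    draws: int | None = None,
) -> np.ndarray:
    """Posterior-predictive trajectories at unseen inputs.

    Sequentially draws Y~_t | Y~_{t-1} from the conditional predictive for each
    stored posterior draw, building the AR design from the emulated lags
    (initialized at ``new_Y0``).  Returns a (draws, T, N~, S) array.  Training
    inputs re-queried reproduce their training trajectories exactly.
    """
    new_inputs = np.atleast_2d(np.asarray(new_inputs, dtype=float))
    n_new = new_inputs.shape[0]
    s_sites = fit.Y[0].shape[1]
    if draws is None:
        draws = fit.result.L
    if n_new == 0:
        return np.empty((draws, fit.T, 0, s_sites))
    new_Y0 = np.asarray(new_Y0, dtype=float).reshape(n_new, s_sites)
    J = sq_exp_corr(fit.inputs, new_inputs, fit.beta)
    V_new = sq_exp_corr(new_inputs, new_inputs, fit.beta)
    out = np.empty((draws, fit.T, n_new, s_sites))
    mnig = fit.result.sigma2 is not None
    for l in range(draws):
        idx = l % fit.result.L
        theta_path = fit.result.thetas[idx]
        if fit.structure == "identity":
            chol_col = np.eye(s_sites)
        elif mnig:
            chol_col = np.sqrt(fit.result.sigma2[idx]) * chol_lower(fit.spec.prior.R)
        else:
            chol_col = np.linalg.cholesky(fit.result.sigmas[idx])
        history = [new_Y0]
        for t in range(1, fit.T + 1):
            F_new = build_ar_design(history, fit.ar_order, t)
            y_new = predictive_conditional(
                F_new, J, V_new, theta_path[t], chol_col,
                fit.Y[t], fit.spec.F[t - 1], fit.V, rng,
            )
            history.append(y_new)
            out[l, t - 1] = y_new
    return out
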