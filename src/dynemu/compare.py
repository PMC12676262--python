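"""Model comparison: WAIC (analytic and Monte-Carlo lppd, with standard
error) and the Gelfand-Ghosh posterior predictive loss D = G + P, for the
three column-covariance structures (inverse-Wishart, sigma^2 R, identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ffbs import DLMSpec, FFBSResult, FilterOutput, SmoothedMoments
from .matdist import (
    MatrixNormalParams,
    logpdf_hyper_t,
    logpdf_hyper_t_scalar,
    logpdf_matrix_normal,
)

__all__ = ["WaicReport", "GpdReport", "waic", "waic_se", "gpd_score"]

_STRUCTURES = ("mniw", "mnig", "identity")


@dataclass
class WaicReport:
    lppd_analytic: float
    lppd_mc: float
    p_waic: float
    waic: float
    se_waic: float
    waic_t: np.ndarray
    structure: str
    lppd_used: str = "analytic"


@dataclass
class GpdReport:
    G: float
    P: float
    D: float
    structure: str


def _structure_of(result: FFBSResult, structure: str | None) -> str:
    if structure is not None:
        if structure not in _STRUCTURES:
            raise ValueError(f"structure must be one of {_STRUCTURES}")
        return structure
    if result.sigma2 is not None:
        return "mnig"
    if result.sigmas is not None:
        return "mniw"
    return "identity"


def _predictive_logpdf(y, loc, row_scale, fo: FilterOutput, spec: DLMSpec, structure):
    """Marginal posterior-predictive log-density of one season."""
    if structure == "mniw":
        return logpdf_hyper_t(y, loc, row_scale, fo.n[-1], fo.D[-1])
    if structure == "mnig":
        return logpdf_hyper_t_scalar(
            y, loc, row_scale, fo.n[-1], fo.d[-1], spec.prior.R
        )
    s = y.shape[1]
    return logpdf_matrix_normal(
        y, MatrixNormalParams(mean=loc, row_cov=row_scale, col_cov=np.eye(s))
    )


def waic(
    result: FFBSResult,
    Y,
    spec: DLMSpec,
    structure: str | None = None,
    use_lppd: str = "analytic",
) -> WaicReport:
    """WAIC = -2 (lppd - p_WAIC).

    The analytic lppd sums the closed-form marginal predictive log-density of
    each season (hyper-T / hyper-T-scalar / matrix-normal by structure) at the
    smoothed moments; the Monte-Carlo lppd is the log-mean-exp of the
    conditional densities over the stored joint draws, and p_WAIC is the
    per-season posterior variance of the conditional log-density, summed.
    """
    structure = _structure_of(result, structure)
    if use_lppd not in ("analytic", "mc"):
        raise ValueError("use_lppd must be 'analytic' or 'mc'")
    L = result.L
    if L < 2:
        raise ValueError("need at least 2 draws to estimate p_WAIC")
    fo, sm = result.filter_out, result.smoothed
    T = fo.T
    Y = [np.asarray(y, dtype=float) for y in Y]

    lppd_analytic_t = np.empty(T)
    lppd_mc_t = np.empty(T)
    p_waic_t = np.empty(T)
    for t in range(1, T + 1):
        F, V = spec.F[t - 1], spec.V[t - 1]
        loc = F @ sm.h[t]
        row_scale = F @ sm.H[t] @ F.T + V
        lppd_analytic_t[t - 1] = _predictive_logpdf(
            Y[t - 1], loc, row_scale, fo, spec, structure
        )
        s_cols = Y[t - 1].shape[1]
        logs = np.empty(L)
        eye_s = np.eye(s_cols)
        for l in range(L):
            mean = F @ result.thetas[l][t]
            col = result.sigmas[l] if structure == "mniw" else (
                result.sigma2[l] * spec.prior.R if structure == "mnig" else eye_s
            )
            logs[l] = logpdf_matrix_normal(
                Y[t - 1], MatrixNormalParams(mean=mean, row_cov=V, col_cov=col)
            )
        m = np.max(logs)
        lppd_mc_t[t - 1] = m + np.log(np.mean(np.exp(logs - m)))
        p_waic_t[t - 1] = float(np.var(logs, ddof=1))
    lppd_analytic = float(np.sum(lppd_analytic_t))
    lppd_mc = float(np.sum(lppd_mc_t))
    p_waic = float(np.sum(p_waic_t))
    lppd_t = lppd_analytic_t if use_lppd == "analytic" else lppd_mc_t
    lppd = lppd_analytic if use_lppd == "analytic" else lppd_mc
    waic_t = -2.0 * (lppd_t - p_waic_t)
    return WaicReport(
        lppd_analytic=lppd_analytic,
        lppd_mc=lppd_mc,
        p_waic=p_waic,
        waic=-2.0 * (lppd - p_waic),
        se_waic=waic_se(waic_t) if T >= 2 else float("nan"),
        waic_t=waic_t,
        structure=structure,
        lppd_used=use_lppd,
    )


def waic_se(waic_t) -> float:
    """Standard error sqrt(T * Var(WAIC_t)) across the per-season terms."""
    waic_t = np.asarray(waic_t, dtype=float)
    T = waic_t.size
    if T < 2:
        raise ValueError("need at least two per-season WAIC terms")
    return float(np.sqrt(T * np.var(waic_t, ddof=1)))


def gpd_score(
    smoothed: SmoothedMoments,
    fo: FilterOutput,
    Y,
    spec: DLMSpec,
    structure: str | None = None,
) -> GpdReport:
    """Gelfand-Ghosh D = G + P with closed-form replicate moments.

    G = sum_t ||Y_t - F_t h_t||_F^2 (structure-free);
    P_IW = tr(D_T)/(n_T - 2) * sum_t tr(H_t),
    P_IG = d_T tr(R)/(n_T - 1) * sum_t tr(H_t),
    P_id = S * sum_t tr(H_t).
    """
    if structure is None:
        structure = "mnig" if fo.is_mnig else "mniw"
    if structure not in _STRUCTURES:
        raise ValueError(f"structure must be one of {_STRUCTURES}")
    Y = [np.asarray(y, dtype=float) for y in Y]
    T = fo.T
    G = 0.0
    tr_h = 0.0  # penalty uses the smoothed state row-covariance traces
    for t in range(1, T + 1):
        resid = Y[t - 1] - spec.F[t - 1] @ smoothed.h[t]
        G += float(np.sum(resid * resid))
        tr_h += float(np.trace(smoothed.H[t]))
    s_cols = Y[0].shape[1]
    if structure == "mniw":
        n_T = fo.n[-1]
        if n_T <= 2:
            raise ValueError("P undefined for inverse-Wishart with n_T <= 2")
        P = float(np.trace(fo.D[-1])) / (n_T - 2.0) * tr_h
    elif structure == "mnig":
        n_T = fo.n[-1]
        if n_T <= 1:
            raise ValueError("P undefined for inverse-gamma with n_T <= 1")
        P = fo.d[-1] * float(np.trace(spec.prior.R)) / (n_T - 1.0) * tr_h
    else:
        P = s_cols * tr_h
    return GpdReport(G=G, P=P, D=G + P, structure=structure)
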