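"""End-to-end runs tying simulate -> emulate -> compare -> calibrate together."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibrate as cal
from . import compare as cmp
from . import mech_sim as ms
from .emulator import emulate, train_emulator
from .interface import RunConfig, provenance, read_matrix, read_tensor, write_matrix, write_tensor

__all__ = ["run_pipeline"]

_LV_MARGINALS = [
    ("lognormal", 0.0, 0.5), ("lognormal", -3.0, 0.5),
    ("lognormal", 0.0, 0.5), ("lognormal", -3.0, 0.5),
]


def _marginals(opts) -> list[tuple]:
    raw = opts.get("marginals")
    if raw is None:
        return list(_LV_MARGINALS)
    return [tuple(m) for m in raw]


def run_pipeline(config: RunConfig) -> dict:
    """Execute one subcommand; artifacts land under ``config.out_dir``.

    Deterministic given (config, seed).  Returns a small summary dict that is
    also written to ``summary.json`` alongside a provenance record.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    opts = config.options
    handler = {
        "simulate": _run_simulate,
        "emulate": _run_emulate,
        "compare": _run_compare,
        "calibrate": _run_calibrate,
    }.get(config.subcommand)
    if handler is None:
        raise ValueError(f"unknown subcommand {config.subcommand!r}")
    summary = handler(opts, out, rng)
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance(config), fh, indent=2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _run_simulate(opts, out: Path, rng) -> dict:
    system = opts.get("system", "lv")
    n = int(opts.get("n_inputs", 20))
    T = int(opts.get("T", 20))
    if system == "lv":
        design = ms.lhs_design(n, _marginals(opts), rng)
        u0, v0 = opts.get("initial_state", (30.0, 4.0))
        tensor = ms.lv_training_tensor(design, u0, v0, T)
    elif system == "sirpde":
        nx, ny = opts.get("grid", (6, 6))
        seeds = opts.get("seeds", [[nx // 2, ny // 2, 0.01], [0, 0, 0.01]])
        design = ms.lhs_design(n, _marginals(opts), rng)
        tensor = ms.sir_training_tensor(
            design, nx, ny, T, seeds, N_pop=float(opts.get("n_pop", 1.0))
        )
    elif system == "network":
        raise ValueError("network runs produce a single trajectory; use the API")
    else:
        raise ValueError(f"unknown system {system!r}")
    write_matrix(out / "design.csv", design)
    write_tensor(out / "tensor.npy", tensor)
    return {"system": system, "tensor_shape": list(tensor.shape)}


def _load_training(opts, out: Path):
    tensor = read_tensor(opts.get("tensor", out / "tensor.npy"))
    design = read_matrix(opts.get("design", out / "design.csv"))
    return tensor, design


def _run_emulate(opts, out: Path, rng) -> dict:
    tensor, design = _load_training(opts, out)
    fit = train_emulator(
        tensor, design, L=int(opts.get("draws", 100)), rng=rng,
        ar_order=int(opts.get("ar_order", 1)),
        beta=opts.get("beta"), structure=opts.get("structure", "mniw"),
    )
    summary = {
        "n_T": fit.result.filter_out.n[-1],
        "T": fit.T,
        "draws": fit.result.L,
    }
    new_inputs = opts.get("new_inputs")
    if new_inputs is not None:
        new_inputs = np.atleast_2d(np.asarray(new_inputs, dtype=float))
        draws = emulate(fit, new_inputs, np.tile(tensor[0, 0], (new_inputs.shape[0], 1)), rng)
        write_tensor(out / "emulation_draws.npy", draws)
        summary["emulated_inputs"] = int(new_inputs.shape[0])
    return summary


def _run_compare(opts, out: Path, rng) -> dict:
    tensor, design = _load_training(opts, out)
    L = int(opts.get("draws", 100))
    rows = {"lppd": {}, "lppd-analytic": {}, "p_WAIC": {}, "WAIC": {}}
    gpd_rows = {"G": {}, "P": {}, "D": {}}
    for structure in ("mniw", "mnig", "identity"):
        fit = train_emulator(
            tensor, design, L=L, rng=np.random.default_rng(rng.integers(2**32)),
            ar_order=int(opts.get("ar_order", 1)), structure=structure,
        )
        rep = cmp.waic(fit.result, fit.Y[1:], fit.spec, structure=structure)
        gpd = cmp.gpd_score(
            fit.result.smoothed, fit.result.filter_out, fit.Y[1:], fit.spec,
            structure=structure,
        )
        rows["lppd"][structure] = rep.lppd_mc
        rows["lppd-analytic"][structure] = rep.lppd_analytic
        rows["p_WAIC"][structure] = rep.p_waic
        rows["WAIC"][structure] = rep.waic
        gpd_rows["G"][structure] = gpd.G
        gpd_rows["P"][structure] = gpd.P
        gpd_rows["D"][structure] = gpd.D
    pd.DataFrame(rows).T.to_csv(out / "waic_table.csv")
    pd.DataFrame(gpd_rows).T.to_csv(out / "gpd_table.csv")
    return {"waic": rows["WAIC"], "D": gpd_rows["D"]}


def _run_calibrate(opts, out: Path, rng) -> dict:
    tensor, design = _load_training(opts, out)
    z = read_matrix(opts["field_data"])
    fit = train_emulator(
        tensor, design, L=int(opts.get("draws", 200)), rng=rng,
        ar_order=int(opts.get("ar_order", 1)),
        structure=opts.get("structure", "mniw"),
    )
    bundle = cal.make_bundle(fit, np.arange(tensor.shape[2]))
    priors = [tuple(p) for p in opts.get("priors", _LV_MARGINALS)]
    config = cal.CalibConfig(
        priors=priors,
        coords=np.arange(tensor.shape[2], dtype=float)[:, None],
        rho=float(opts.get("rho", 1.5)),
        fix_rho=bool(opts.get("fix_rho", True)),
        bias_modularized=bool(opts.get("bias_modularized", False)),
    )
    iters = int(opts.get("iters", 1000))
    traces = cal.run_calibration(z, bundle, config, iters, rng)
    keep = traces["eta"][traces["burn_in"]:]
    q = np.quantile(keep, [0.5, 0.025, 0.975], axis=0)
    summary_df = pd.DataFrame(
        {"median": q[0], "q2.5": q[1], "q97.5": q[2]},
        index=[f"eta{i + 1}" for i in range(keep.shape[1])],
    )
    summary_df.to_csv(out / "calibration_summary.csv")
    write_tensor(out / "eta_trace.npy", traces["eta"])
    return {
        "accept_rate": traces["accept_rate"],
        "medians": q[0].tolist(),
    }
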