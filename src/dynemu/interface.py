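"""Configuration, file I/O and pipeline plumbing.

JSON run configurations are schema-checked (unknown keys rejected), 2-D
matrices travel as delimited text with a shape header, higher-order tensors
as .npy binary, and every pipeline run records a provenance stamp
(config hash, package version, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RunConfig",
    "load_config",
    "write_matrix",
    "read_matrix",
    "write_tensor",
    "read_tensor",
    "provenance",
]

_ALLOWED_KEYS = {
    "subcommand", "out_dir", "seed", "structure", "system",
    "n_inputs", "T", "grid", "seeds", "ar_order", "beta", "draws",
    "rows_per_episode", "cols_per_episode", "priors", "rho", "fix_rho",
    "iters", "field_data", "design", "tensor", "new_inputs", "marginals",
    "bias_modularized", "initial_state", "n_pop",
}
_REQUIRED_KEYS = {"subcommand", "seed", "out_dir"}
_STRUCTURES = ("mniw", "mnig", "identity")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    subcommand: str
    seed: int
    out_dir: str
    options: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = _REQUIRED_KEYS - set(raw)
        if missing:
            raise ValueError(f"missing config keys: {sorted(missing)}")
        if not isinstance(raw["seed"], int):
            raise ValueError("config field 'seed': must be an integer")
        if raw.get("structure", "mniw") not in _STRUCTURES:
            raise ValueError(
                f"config field 'structure': must be one of {_STRUCTURES}"
            )
        opts = {k: v for k, v in raw.items() if k not in _REQUIRED_KEYS}
        return cls(
            subcommand=raw["subcommand"], seed=raw["seed"],
            out_dir=raw["out_dir"], options=opts,
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(json.load(fh))


def write_matrix(path: str | Path, mat: np.ndarray, colnames=None) -> None:
    """Delimited text with a '# shape: r c' header comment."""
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    header = f"shape: {mat.shape[0]} {mat.shape[1]}"
    if colnames is not None:
        header += "\n" + ",".join(map(str, colnames))
    np.savetxt(path, mat, delimiter=",", header=header)


def read_matrix(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# shape:"):
        raise ValueError(f"{path}: missing '# shape:' header")
    r, c = map(int, first.split(":")[1].split())
    mat = np.atleast_2d(np.loadtxt(path, delimiter=",", comments="#"))
    if mat.shape != (r, c):
        raise ValueError(f"{path}: header says {(r, c)}, data is {mat.shape}")
    return mat


def write_tensor(path: str | Path, tensor: np.ndarray) -> None:
    np.save(path, np.asarray(tensor, dtype=float), allow_pickle=False)


def read_tensor(path: str | Path) -> np.ndarray:
    return np.load(path, allow_pickle=False)


def provenance(config: RunConfig) -> dict:
    from . import __version__

    blob = json.dumps(
        {"subcommand": config.subcommand, "seed": config.seed, **config.options},
        sort_keys=True,
    )
    return {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
    }
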