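"""Bundled reference data."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_lynx_hare"]


def load_lynx_hare() -> pd.DataFrame:
    """Annual Canadian snowshoe-hare and lynx records, 1900-1920.

    The classical Hudson Bay Company series (populations in thousands);
    columns ``year``, ``hare`` (prey) and ``lynx`` (predator).
    """
    with resources.files("dynemu.data").joinpath("lynx_hare.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.astype({"year": int, "hare": float, "lynx": float})


def lynx_hare_log_matrix() -> np.ndarray:
    """(T+1, 2) log-population matrix, rows 1900..1920, columns (hare, lynx)."""
    df = load_lynx_hare()
    return np.log(df[["hare", "lynx"]].to_numpy())
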