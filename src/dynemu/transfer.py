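"""Season/episode Bayesian transfer learning.

Partitions each season's N x S output matrix into K = k1*k2 episode blocks of
size r x c and streams them through the conjugate FFBS machinery as K*T
sequential pseudo-times, retaining a shared c x c column covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .emulator import build_ar_design
from .ffbs import DLMSpec, FFBSResult, ffbs, forward_filter
from .matdist import MNIGState, MNIWState

__all__ = [
    "PartitionSpec",
    "Episode",
    "EpisodeStream",
    "parent_index",
    "partition_stream",
    "streaming_ffbs",
    "reassemble_forecasts",
]


@dataclass(frozen=True)
class PartitionSpec:
    """Episode tiling: r rows x c columns per episode of an N x S season."""

    N: int
    S: int
    r: int
    c: int

    def __post_init__(self) -> None:
        if self.N % self.r or self.S % self.c:
            raise ValueError(
                f"partition {self.r}x{self.c} does not tile a {self.N}x{self.S} matrix"
            )

    @property
    def k1(self) -> int:
        return self.N // self.r

    @property
    def k2(self) -> int:
        return self.S // self.c

    @property
    def K(self) -> int:
        return self.k1 * self.k2


def parent_index(k: int, t: int, K: int) -> tuple[int, int]:
    """Stream predecessor of episode (k, t), 1-based.

    (k-1, t) for k >= 2; (K, t-1) for k = 1, t >= 2; (0, 0) for k = t = 1.
    """
    if not (1 <= k <= K) or t < 1:
        raise IndexError(f"episode index ({k}, {t}) out of range for K={K}")
    if k >= 2:
        return (k - 1, t)
    if t >= 2:
        return (K, t - 1)
    return (0, 0)


@dataclass
class Episode:
    """One streamed block D_{k,t} = (Y, F, G, V, W) with its parent link."""

    k: int
    t: int
    Y: np.ndarray
    F: np.ndarray
    G: np.ndarray
    V: np.ndarray
    W: np.ndarray
    parent: tuple[int, int]


@dataclass
class EpisodeStream:
    """Ordered episodes (k fastest within season) plus partition metadata."""

    episodes: list[Episode]
    part: PartitionSpec
    T: int

    def __len__(self) -> int:
        return len(self.episodes)

    @property
    def K(self) -> int:
        return self.part.K


def _row_slices(part: PartitionSpec) -> list[slice]:
    return [slice(i * part.r, (i + 1) * part.r) for i in range(part.k1)]


def _col_slices(part: PartitionSpec) -> list[slice]:
    return [slice(j * part.c, (j + 1) * part.c) for j in range(part.k2)]


def partition_stream(
    Y: Sequence[np.ndarray],
    F,
    G,
    V,
    W,
    part: PartitionSpec,
    Y0: np.ndarray | None = None,
    ar_order: int | None = None,
    within_season_transition: bool = False,
    within_season_W: str = "full",
) -> EpisodeStream:
    """Tile each season into episodes and order them into a stream.

    Within a season the column-blocks vary fastest, then the row-blocks, so
    that an (r=N, c) partition walks the columns of the output left to right.
    ``F`` is either a per-time sequence of N x p design matrices (sliced by
    row-block, shared across column blocks) or the string ``"ar"`` in which
    case the per-episode design is built from the *same* (row, column) block
    of the previous ``ar_order`` seasons, padding with the matching block of
    ``Y0``.  The season-level transition (G_t, W_t) fires at the first episode
    of each season; within a season G defaults to identity and W to W_t
    (``within_season_W="zero"`` suppresses within-season innovation, the
    exact-reduction configuration).
    """
    T = len(Y)
    Y = [np.asarray(y, dtype=float) for y in Y]
    if within_season_W not in ("full", "zero"):
        raise ValueError("within_season_W must be 'full' or 'zero'")
    ar_mode = isinstance(F, str)
    if ar_mode:
        if F != "ar":
            raise ValueError("F must be per-time matrices or the string 'ar'")
        if Y0 is None or ar_order not in (1, 2):
            raise ValueError("AR mode needs Y0 and ar_order in {1, 2}")
        Y0 = np.asarray(Y0, dtype=float)

    def per_time(x, t):
        return x if isinstance(x, np.ndarray) else x[t]

    rows, cols = _row_slices(part), _col_slices(part)
    episodes: list[Episode] = []
    for t in range(T):
        Gt, Wt, Vt = per_time(G, t), per_time(W, t), per_time(V, t)
        k = 0
        for i, rs in enumerate(rows):
            for j, cs in enumerate(cols):
                k += 1
                first = k == 1
                if ar_mode:
                    block_hist = [Y0[rs, cs]] + [Y[u][rs, cs] for u in range(T)]
                    Fkt = build_ar_design(block_hist, ar_order, t + 1)
                else:
                    Fkt = per_time(F, t)[rs, :]
                p = Fkt.shape[1]
                if first:
                    Gkt, Wkt = Gt, Wt
                else:
                    Gkt = Gt if within_season_transition else np.eye(p)
                    Wkt = Wt if within_season_W == "full" else np.zeros((p, p))
                episodes.append(
                    Episode(
                        k=k, t=t + 1, Y=Y[t][rs, cs], F=Fkt, G=Gkt,
                        V=Vt[rs, rs], W=Wkt,
                        parent=parent_index(k, t + 1, part.K),
                    )
                )
    return EpisodeStream(episodes=episodes, part=part, T=T)


def stream_spec(stream: EpisodeStream, prior) -> tuple[list, DLMSpec]:
    """Flatten an episode stream to (observations, DLMSpec) over KT pseudo-times."""
    return _stream_spec(stream, prior)


def _stream_spec(stream: EpisodeStream, prior) -> tuple[list, DLMSpec]:
    Ys = [ep.Y for ep in stream.episodes]
    spec = DLMSpec(
        F=[ep.F for ep in stream.episodes],
        G=[ep.G for ep in stream.episodes],
        V=[ep.V for ep in stream.episodes],
        W=[ep.W for ep in stream.episodes],
        prior=prior,
        T=len(stream.episodes),
    )
    return Ys, spec


def streaming_ffbs(
    stream: EpisodeStream,
    prior: MNIWState | MNIGState,
    L: int,
    rng: np.random.Generator,
    fixed_sigma: np.ndarray | None = None,
) -> FFBSResult:
    """Run FFBS over the episode stream as K*T sequential pseudo-times.

    With K = 1 this is the plain FFBS on the original sequence, bit for bit.
    The column covariance posterior has the episode column dimension c.
    """
    c = prior.shape[1]
    if c != stream.part.c:
        raise ValueError(
            f"prior column dimension {c} must equal episode columns {stream.part.c}"
        )
    Ys, spec = _stream_spec(stream, prior)
    return ffbs(Ys, spec, L, rng, fixed_sigma=fixed_sigma)


def streaming_filter(stream: EpisodeStream, prior):
    """Forward filter only, over the episode stream."""
    Ys, spec = _stream_spec(stream, prior)
    return forward_filter(Ys, spec), spec


def reassemble_forecasts(stream: EpisodeStream, filter_out) -> list[np.ndarray]:
    """Concatenate episode one-step forecasts q_{k,t} back to N x S per season."""
    part = stream.part
    rows, cols = _row_slices(part), _col_slices(part)
    out = [np.full((part.N, part.S), np.nan) for _ in range(stream.T)]
    for idx, ep in enumerate(stream.episodes):
        i, j = divmod(ep.k - 1, part.k2)
        out[ep.t - 1][rows[i], cols[j]] = filter_out.q[idx + 1]
    return out
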