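"""Delay-coordinate reconstruction of attractors (Takens embedding).

A scalar observable ``x`` of a deterministic system is unfolded into delay
vectors ``[x(t), x(t+tau), ..., x(t+(D-1)tau)]``. By Takens' theorem the
resulting point cloud is homeomorphic to the attractor of the full system, so
geometric relations between time points in the reconstruction mirror those in
the (unobserved) state space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "EmbeddingParams",
    "DelayEmbedding",
    "delay_embed",
    "select_embedding_params",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding dimension ``dim`` (D) and delay ``lag`` (tau, in samples)."""

    dim: int
    lag: int

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.lag < 1:
            raise ValueError("embedding lag must be >= 1")

    @property
    def span(self) -> int:
        """Samples consumed by one delay vector minus one: (D-1)*tau."""
        return (self.dim - 1) * self.lag


@dataclass
class DelayEmbedding:
    """Matrix of delay vectors plus the time index of each vector's first coordinate."""

    points: np.ndarray  # (n_points, dim)
    times: np.ndarray  # (n_points,) index of first coordinate
    params: EmbeddingParams

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _as_channel(series, channel=0) -> np.ndarray:
    if isinstance(series, TimeSeries):
        return series.channel(channel)
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single channel (1-D array)")
    return x


def delay_embed(series, params: EmbeddingParams, channel: int | str = 0) -> DelayEmbedding:
    """Build the delay reconstruction of one channel.

    Row ``i`` is ``[x(i), x(i+tau), ..., x(i+(D-1)tau)]``; rows are returned in
    temporal order and no normalization is applied here.

    Raises
    ------
    ValueError
        If the series is too short for the requested ``(dim, lag)``.
    """
    x = _as_channel(series, channel)
    L = len(x)
    if params.span >= L:
        raise ValueError(
            f"series of length {L} too short for dim={params.dim}, lag={params.lag}: "
            f"needs length > (dim-1)*lag = {params.span}"
        )
    n = L - params.span
    cols = [x[k * params.lag : k * params.lag + n] for k in range(params.dim)]
    return DelayEmbedding(
        points=np.column_stack(cols), times=np.arange(n), params=params
    )


def _lagged_mutual_information(x: np.ndarray, lag: int, bins: int) -> float:
    a, b = x[:-lag], x[lag:]
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _lag_first_mi_minimum(x: np.ndarray, max_lag: int) -> int | None:
    bins = max(8, int(np.sqrt(len(x) / 5)))
    mi = np.array(
        [_lagged_mutual_information(x, lag, bins) for lag in range(1, max_lag + 1)]
    )
    if len(mi) >= 3:  # 3-point smoothing guards against histogram jitter
        mi = np.convolve(mi, np.ones(3) / 3, mode="same")
    for k in range(1, len(mi) - 1):
        if mi[k] < mi[k - 1] and mi[k] <= mi[k + 1]:
            return k + 1
    return None


def _lag_autocorr_zero_crossing(x: np.ndarray, max_lag: int) -> int:
    xc = x - x.mean()
    denom = float(xc @ xc)
    for lag in range(1, max_lag + 1):
        if xc[:-lag] @ xc[lag:] / denom <= 0:
            return lag
    return max_lag


def _fnn_fraction(
    x: np.ndarray, dim: int, lag: int, rtol: float = 15.0, atol: float = 2.0
) -> float:
    """Kennel false-nearest-neighbor fraction going from ``dim`` to ``dim+1``."""
    from scipy.spatial import cKDTree

    emb = delay_embed(x, EmbeddingParams(dim, lag))
    n_next = len(x) - dim * lag  # points that survive in dim+1
    pts = emb.points[:n_next]
    if len(pts) < 3:
        return 1.0
    tree = cKDTree(pts)
    dists, idx = tree.query(pts, k=2)
    d, nn = dists[:, 1], idx[:, 1]
    extra = np.abs(
        x[np.arange(n_next) + dim * lag] - x[nn + dim * lag]
    )
    sd = x.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        false = (extra / np.where(d > 0, d, np.inf) > rtol) | (
            np.sqrt(d**2 + extra**2) / sd > atol
        )
    return float(false.mean())


def select_embedding_params(
    series,
    max_dim: int = 8,
    max_lag: int = 50,
    channel: int | str = 0,
    fnn_threshold: float = 0.05,
    dim: int | None = None,
    lag: int | None = None,
) -> EmbeddingParams:
    """Heuristic (D, tau) selection; explicit ``dim``/``lag`` override the heuristics.

    The delay is the first local minimum of the lagged mutual information
    (falling back to the first zero-crossing of the autocorrelation when no
    minimum exists within ``max_lag``); the dimension is the smallest D whose
    false-nearest-neighbor fraction drops below ``fnn_threshold`` (capped at
    ``max_dim`` with a warning — typical for stochastic signals, where the FNN
    criterion never stabilizes).
    """
    x = _as_channel(series, channel)
    if x.std() == 0:
        raise ValueError("cannot select embedding parameters for a constant series")
    if dim is not None and lag is not None:
        return EmbeddingParams(dim, lag)
    if len(x) <= max_dim * max_lag:
        raise ValueError("series too short for the requested search ranges")

    if lag is None:
        lag = _lag_first_mi_minimum(x, max_lag)
        if lag is None:
            lag = _lag_autocorr_zero_crossing(x, max_lag)

    if dim is None:
        for d in range(1, max_dim):
            if _fnn_fraction(x, d, lag) < fnn_threshold:
                dim = d
                break
        else:
            warnings.warn(
                f"false-nearest-neighbor fraction never fell below {fnn_threshold}; "
                f"using max_dim={max_dim}",
                stacklevel=2,
            )
            dim = max_dim
    return EmbeddingParams(dim, lag)
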