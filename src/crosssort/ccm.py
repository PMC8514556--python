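"""Convergent cross mapping (CCM) baseline.

CCM tests for coupling by cross-predicting one variable from the nearest
neighbors of contemporaneous points in the other variable's delay
reconstruction: the D+1 nearest neighbors of x_t in M_X are mapped to their
y values and combined with exponentially decaying weights; the skill
corr(y*_t, y_t) is the CCM score. Following the standard convention,
estimating y from M_X quantifies y -> x coupling (the driven variable's
manifold contains the driver), so the reported score(x -> y) is the skill of
estimating x from M_Y.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist

from .ccs import CouplingScore
from .embedding import DelayEmbedding, EmbeddingParams, delay_embed
from .timeseries import zscore

__all__ = ["cross_map_estimate", "ccm"]


def _neighbor_weights(d: np.ndarray) -> np.ndarray:
    """Exponential weights exp(-d_i/d_1), normalized; exact matches collapse the weight."""
    d1 = d[0]
    if d1 == 0:
        w = (d == 0).astype(float)
    else:
        w = np.exp(-d / d1)
    return w / w.sum()


def cross_map_estimate(
    mx: DelayEmbedding,
    y_values: np.ndarray,
    t: int,
    k: int | None = None,
    exclusion_window: int = 0,
) -> float:
    """Estimate y at embedding time ``t`` from the neighbors of x_t in M_X.

    Finds the ``k`` nearest neighbors of the delay vector at time ``t``
    (default ``k = D + 1``), excluding any neighbor within
    ``exclusion_window`` of ``t``; the estimate is the exponentially weighted
    average of the neighbors' y values.
    """
    if k is None:
        k = mx.params.dim + 1
    pos = int(np.searchsorted(mx.times, t))
    if pos >= mx.n_points or mx.times[pos] != t:
        raise ValueError(f"time {t} not present in the embedding")
    d = np.linalg.norm(mx.points - mx.points[pos], axis=1)
    admissible = np.abs(mx.times - t) > exclusion_window
    if admissible.sum() < k:
        raise ValueError(f"fewer than k={k} admissible neighbors for t={t}")
    idx = np.where(admissible)[0]
    order = idx[np.argsort(d[idx], kind="stable")][:k]
    w = _neighbor_weights(d[order])
    return float(w @ np.asarray(y_values, dtype=float)[mx.times[order]])


def _cross_map_all(
    m: DelayEmbedding, target: np.ndarray, k: int, exclusion_window: int
) -> np.ndarray:
    """Vectorized cross-map of every admissible embedding time."""
    D = cdist(m.points, m.points)
    dt = np.abs(m.times[:, None] - m.times[None, :])
    D[dt <= exclusion_window] = np.inf
    # neighbors per row
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    d = np.take_along_axis(D, order, axis=1)
    if not np.all(np.isfinite(d)):
        raise ValueError(f"fewer than k={k} admissible neighbors for some time point")
    d1 = d[:, :1]
    w = np.where(d1 > 0, np.exp(-d / np.where(d1 > 0, d1, 1.0)), (d == 0).astype(float))
    w /= w.sum(axis=1, keepdims=True)
    return np.sum(w * target[m.times[order]], axis=1)


def ccm(
    x,
    y,
    params: EmbeddingParams | tuple[EmbeddingParams, EmbeddingParams],
    direction: str = "both",
    k: int | None = None,
    exclusion_window: int | None = None,
    standardize: bool = True,
    labels: tuple[str, str] = ("x", "y"),
) -> CouplingScore | dict[str, CouplingScore]:
    """CCM coupling score(s) between two equal-length scalar series.

    score(x -> y) is the Pearson correlation between x and its cross-map
    estimate from M_Y. Zero-variance estimates yield a score of 0 with a
    warning. Defaults (exclusion window, standardization) match the CCS
    scorer so that method comparisons differ only in the correspondence
    statistic.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    px, py = params if isinstance(params, tuple) else (params, params)
    if exclusion_window is None:
        exclusion_window = px.dim * px.lag
    if standardize:
        x, y = zscore(x), zscore(y)

    def skill(m: DelayEmbedding, target: np.ndarray, kk: int) -> float:
        est = _cross_map_all(m, target, kk, exclusion_window)
        truth = target[m.times]
        if est.std() == 0 or truth.std() == 0:
            warnings.warn("zero-variance cross-map estimates; score set to 0", stacklevel=3)
            return 0.0
        return float(np.clip(np.corrcoef(est, truth)[0, 1], -1.0, 1.0))

    def one(d: str) -> CouplingScore:
        if d == "x_to_y":  # influence of x on y: estimate x from M_Y
            value = skill(delay_embed(y, py), x, k or py.dim + 1)
            src, tgt = labels
        elif d == "y_to_x":
            value = skill(delay_embed(x, px), y, k or px.dim + 1)
            src, tgt = labels[1], labels[0]
        else:
            raise ValueError(f"unknown direction {d!r}")
        return CouplingScore(source=src, target=tgt, method="ccm", value=value)

    if direction == "both":
        return {d: one(d) for d in ("x_to_y", "y_to_x")}
    return one(direction)
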