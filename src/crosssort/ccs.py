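"""Convergent cross sorting (CCS).

CCS tests whether two delay reconstructions M_X and M_Y are smoothly mapped
onto one another by comparing the *ranks* of the pairwise distances between
the same time points in each manifold. For every admissible pair of time
points (i, j) the Euclidean distances d_X(i,j) and d_Y(i,j) are ranked within
their own manifold; the signed rank error ERR = R_X - R_Y is accumulated in
conditioning-rank order, normalized against the expectation for uncorrelated
ranks (NERR^2 = (null - ERR^2)/null), and the cumulative average curve is
extrapolated to rank zero with an exponential fit. The y-intercept of that
fit is the CCS score: 1 for perfect rank correspondence, 0 at chance.

Direction convention: ``score(x -> y)`` quantifies the influence of x on y.
If x drives y, the manifold of the driven variable y reconstructs the joint
system, so low ranks in M_Y predict low ranks in M_X; the x -> y error curve
is therefore conditioned on R_Y (and y -> x on R_X).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .embedding import DelayEmbedding, EmbeddingParams, delay_embed
from .timeseries import zscore

__all__ = [
    "RankCorrespondence",
    "ErrorCurve",
    "CouplingScore",
    "pairwise_rank_distances",
    "rank_error",
    "null_err2",
    "nerr2_curve",
    "ccs_score_from_curve",
    "ccs",
    "ccs_significance",
    "DEFAULT_MAX_RANK_FRAC",
    "DEFAULT_PAIR_BUDGET",
]

DEFAULT_MAX_RANK_FRAC = 0.25
DEFAULT_PAIR_BUDGET = 2_000_000


@dataclass
class RankCorrespondence:
    """Matched ranks of pairwise distances in two reconstructions.

    ``rank_x[k]`` and ``rank_y[k]`` are the ranks (ascending, ties averaged)
    of the distance between the same time-point pair ``pair_index[:, k]`` in
    M_X and M_Y respectively.
    """

    rank_x: np.ndarray
    rank_y: np.ndarray
    pair_index: np.ndarray  # (2, n_pairs) time-point indices

    @property
    def n_pairs(self) -> int:
        return len(self.rank_x)


@dataclass
class ErrorCurve:
    """Cumulative average of NERR^2 on a normalized conditioning-rank grid."""

    rank_grid: np.ndarray  # normalized ranks in (0, 1]
    cum_nerr2: np.ndarray
    null_value: float


@dataclass
class CouplingScore:
    """A directed coupling score for an ordered variable pair."""

    source: str
    target: str
    method: str  # "ccs" | "ccm"
    value: float
    fit_ok: bool = True
    p_value: float | None = None


def pairwise_rank_distances(
    mx: DelayEmbedding,
    my: DelayEmbedding,
    exclusion_window: int = 0,
    max_pairs: int = DEFAULT_PAIR_BUDGET,
    rng: np.random.Generator | None = None,
) -> RankCorrespondence:
    """Rank the pairwise distances between common time points of two embeddings.

    Both embeddings are restricted to their common retained time indices.
    Pairs (i, j) with ``|i - j| <= exclusion_window`` are dropped (Theiler-style
    temporal exclusion) so trivially close temporal neighbors cannot dominate
    the low ranks. When more than ``max_pairs`` pairs remain they are uniformly
    subsampled with ``rng`` (an approximation; the default budget is far above
    anything reached at typical lengths).
    """
    if exclusion_window < 0:
        raise ValueError("exclusion_window must be >= 0")
    common, ix, iy = np.intersect1d(mx.times, my.times, return_indices=True)
    X, Y = mx.points[ix], my.points[iy]
    n = len(common)
    ii, jj = np.triu_indices(n, k=1)
    keep = (common[jj] - common[ii]) > exclusion_window
    ii, jj = ii[keep], jj[keep]
    if len(ii) < 2:
        raise ValueError(
            "fewer than 2 admissible time-point pairs after temporal exclusion"
        )
    dX = pdist(X)[keep]
    dY = pdist(Y)[keep]
    if len(ii) > max_pairs:
        rng = rng or np.random.default_rng()
        sel = rng.choice(len(ii), size=max_pairs, replace=False)
        ii, jj, dX, dY = ii[sel], jj[sel], dX[sel], dY[sel]
    if not dX.any() or not dY.any():
        raise ValueError("degenerate input: all pairwise distances are zero in one manifold")
    return RankCorrespondence(
        rank_x=rankdata(dX),
        rank_y=rankdata(dY),
        pair_index=np.vstack([common[ii], common[jj]]),
    )


def rank_error(rc: RankCorrespondence, direction: str = "x_to_y") -> np.ndarray:
    """Signed rank errors ERR = R_X - R_Y in conditioning-rank order.

    For ``x_to_y`` the errors are ordered by R_Y (the ranks in the manifold of
    the driven variable y); for ``y_to_x`` by R_X.
    """
    err = rc.rank_x - rc.rank_y
    if direction == "x_to_y":
        cond = rc.rank_y
    elif direction == "y_to_x":
        cond = rc.rank_x
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return err[np.argsort(cond, kind="stable")]


def null_err2(n_pairs: int, mode: str = "marginal", rank: float | None = None) -> float:
    """Expected squared rank error for uncorrelated ranks.

    ``marginal``: E[(R_X - R_Y)^2] = (n^2 - 1)/6 for two independent uniform
    rank permutations of size n. ``conditional``: E[(R_X - r)^2] =
    (n^2 - 1)/12 + ((n + 1)/2 - r)^2 for a given conditioning rank r.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    n = n_pairs
    if mode == "marginal":
        return (n**2 - 1) / 6.0
    if mode == "conditional":
        if rank is None:
            raise ValueError("conditional null requires a conditioning rank")
        return (n**2 - 1) / 12.0 + ((n + 1) / 2.0 - rank) ** 2
    raise ValueError(f"unknown null mode {mode!r}")


def nerr2_curve(err: np.ndarray, null: float) -> ErrorCurve:
    """Normalize squared errors against ``null`` and cumulatively average them.

    ``cum_nerr2[k]`` is the mean of NERR^2 = (null - ERR^2)/null over the k+1
    lowest conditioning ranks; the rank grid is normalized to (0, 1].
    """
    err = np.asarray(err, dtype=float)
    if err.size == 0:
        raise ValueError("empty error vector")
    if null <= 0:
        raise ValueError("null must be positive")
    nerr2 = (null - err**2) / null
    k = np.arange(1, err.size + 1)
    return ErrorCurve(
        rank_grid=k / err.size,
        cum_nerr2=np.cumsum(nerr2) / k,
        null_value=float(null),
    )


def _exp_model(r, a, b, c):
    return a * np.exp(-b * r) + c


def ccs_score_from_curve(
    curve: ErrorCurve,
    max_rank_frac: float = DEFAULT_MAX_RANK_FRAC,
) -> tuple[float, bool]:
    """Extrapolate the cumulative NERR^2 curve to rank zero.

    The curve is thresholded at ``max_rank_frac`` and fit with
    ``a*exp(-b*r) + c`` (b >= 0) by least squares; the score is the
    y-intercept ``a + c`` clipped to [-1, 1]. On non-convergence the intercept
    of a linear fit on the lowest-decile points is used and ``fit_ok`` is
    False. Returns ``(score, fit_ok)``.
    """
    if not 0 < max_rank_frac <= 1:
        raise ValueError("max_rank_frac must be in (0, 1]")
    sel = curve.rank_grid <= max_rank_frac
    r, y = curve.rank_grid[sel], curve.cum_nerr2[sel]
    if len(r) < 3:
        raise ValueError(
            f"fewer than 3 curve points at or below max_rank_frac={max_rank_frac}"
        )
    if np.ptp(y) < 1e-12:
        return float(np.clip(y[0], -1.0, 1.0)), True
    try:
        p0 = (y[0] - y[-1], 1.0, y[-1])
        popt, _ = curve_fit(
            _exp_model,
            r,
            y,
            p0=p0,
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        a, _, c = popt
        return float(np.clip(a + c, -1.0, 1.0)), True
    except (RuntimeError, ValueError):
        m = max(2, len(r) // 10)
        coef = np.polyfit(r[:m], y[:m], 1)
        return float(np.clip(coef[1], -1.0, 1.0)), False


def _prepare_embeddings(
    x: np.ndarray,
    y: np.ndarray,
    params: EmbeddingParams | tuple[EmbeddingParams, EmbeddingParams],
    standardize: bool,
) -> tuple[DelayEmbedding, DelayEmbedding]:
    px, py = params if isinstance(params, tuple) else (params, params)
    if standardize:
        x, y = zscore(x), zscore(y)
    return delay_embed(x, px), delay_embed(y, py)


def ccs(
    x,
    y,
    params: EmbeddingParams | tuple[EmbeddingParams, EmbeddingParams],
    direction: str = "both",
    exclusion_window: int | None = None,
    max_rank_frac: float = DEFAULT_MAX_RANK_FRAC,
    null_mode: str = "conditional",
    standardize: bool = True,
    max_pairs: int = DEFAULT_PAIR_BUDGET,
    rng: np.random.Generator | None = None,
    labels: tuple[str, str] = ("x", "y"),
) -> CouplingScore | dict[str, CouplingScore]:
    """CCS coupling score(s) between two equal-length scalar series.

    Composes embedding, pairwise rank correspondence, rank-error curve and
    exponential extrapolation. ``direction`` is ``"x_to_y"``, ``"y_to_x"`` or
    ``"both"`` (returning a dict keyed by direction). The default temporal
    exclusion window is ``dim * lag`` of the x-embedding.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    px = params[0] if isinstance(params, tuple) else params
    if exclusion_window is None:
        exclusion_window = px.dim * px.lag
    mx, my = _prepare_embeddings(x, y, params, standardize)
    rc = pairwise_rank_distances(mx, my, exclusion_window, max_pairs, rng)
    null = null_err2(rc.n_pairs, mode="marginal")

    def one(d: str) -> CouplingScore:
        err = rank_error(rc, d)
        if null_mode == "conditional":
            cond = np.sort(rc.rank_y if d == "x_to_y" else rc.rank_x, kind="stable")
            n = rc.n_pairs
            nulls = (n**2 - 1) / 12.0 + ((n + 1) / 2.0 - cond) ** 2
            k = np.arange(1, err.size + 1)
            curve = ErrorCurve(
                k / err.size, np.cumsum((nulls - err**2) / nulls) / k, float(nulls.mean())
            )
        else:
            curve = nerr2_curve(err, null)
        value, ok = ccs_score_from_curve(curve, max_rank_frac)
        src, tgt = (labels[0], labels[1]) if d == "x_to_y" else (labels[1], labels[0])
        return CouplingScore(source=src, target=tgt, method="ccs", value=value, fit_ok=ok)

    if direction == "both":
        return {d: one(d) for d in ("x_to_y", "y_to_x")}
    return one(direction)


def ccs_significance(
    x,
    y,
    params: EmbeddingParams,
    direction: str = "x_to_y",
    n_surrogates: int = 99,
    seed: int | None = None,
    exclusion_window: int | None = None,
    **kwargs,
) -> tuple[float, float]:
    """One-sided surrogate test for a CCS score.

    Surrogates are random circular shifts of ``y``, which preserve each
    series' dynamics while destroying their temporal alignment. The minimum
    shift exceeds both the exclusion window and a tenth of the series length:
    for deterministic series a slightly shifted copy is still genuinely
    coupled to the original (rank correspondence decays only at the rate of
    trajectory divergence), so small shifts would not be null. Returns
    ``(observed_score, p_value)`` with the plus-one estimator
    ``p = (1 + #{surrogate >= observed}) / (1 + n_surrogates)``, so p is
    never 0.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    px = params[0] if isinstance(params, tuple) else params
    if exclusion_window is None:
        exclusion_window = px.dim * px.lag
    L = len(x)
    if L < 3 * (exclusion_window + 1):
        raise ValueError("series too short relative to the exclusion window")
    min_shift = max(exclusion_window + 1, L // 10)
    rng = np.random.default_rng(seed)
    obs = ccs(x, y, params, direction, exclusion_window, **kwargs).value
    exceed = 0
    for _ in range(n_surrogates):
        shift = int(rng.integers(min_shift, L - min_shift + 1))
        surr = ccs(x, np.roll(y, shift), params, direction, exclusion_window, **kwargs).value
        if surr >= obs:
            exceed += 1
    return obs, (1 + exceed) / (1 + n_surrogates)
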