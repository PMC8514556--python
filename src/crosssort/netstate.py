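"""Sliding-window network-state analysis of three-channel signals.

Every window of every epoch is summarized by the 6-dimensional vector of
directed CCS scores among the three channels. The score vectors are
normalized, whitened and quantized with k-means into a small number of
network states; each epoch then becomes a short symbolic sequence of states.
Because epochs are cut from longer events, the phase of a sequence carries
no information and cyclic permutations are treated as the same pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .ccs import ccs
from .embedding import EmbeddingParams

__all__ = [
    "PAIR_ORDER",
    "WindowedScores",
    "windowed_ccs",
    "cluster_states",
    "canonical_cycle",
    "n_canonical_sequences",
    "sequence_statistics",
]

#: Ordered-pair layout of the 6-dimensional score vector for 3 channels.
PAIR_ORDER = [(i, j) for i in range(3) for j in range(3) if i != j]


@dataclass
class WindowedScores:
    """epochs x windows x 6 tensor of directed CCS scores."""

    scores: np.ndarray  # (n_epochs, n_windows, 6)
    window_len: int
    step: int
    labels: list = field(default=None)  # type: ignore[assignment]  # condition tag per epoch

    def __post_init__(self) -> None:
        if self.scores.ndim != 3 or self.scores.shape[2] != len(PAIR_ORDER):
            raise ValueError("scores must have shape (n_epochs, n_windows, 6)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores contain non-finite values")
        if self.labels is None:
            self.labels = [None] * self.scores.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.scores.reshape(-1, self.scores.shape[2])


def windowed_ccs(
    values: np.ndarray,
    epoch_len: int,
    window_len: int,
    step: int | None = None,
    n_windows: int = 3,
    params: EmbeddingParams | None = None,
    labels=None,
    **ccs_kwargs,
) -> WindowedScores:
    """Directed CCS scores in sliding windows of consecutive epochs.

    ``values`` is (L, 3); it is cut into epochs of ``epoch_len`` samples, and
    within each epoch ``n_windows`` windows of ``window_len`` samples tile the
    epoch (``step`` defaults to ``(epoch_len - window_len) // (n_windows-1)``).
    All 6 directed CCS scores are computed per window.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 3:
        raise ValueError("expected a (L, 3) three-channel array")
    params = params or EmbeddingParams(dim=2, lag=1)
    min_len = params.span + 8
    if window_len < min_len:
        raise ValueError(
            f"window_len={window_len} too short for dim={params.dim}, lag={params.lag}; "
            f"minimum is {min_len} samples"
        )
    if epoch_len < window_len:
        raise ValueError("epoch_len must be >= window_len")
    if step is None:
        step = (epoch_len - window_len) // (n_windows - 1) if n_windows > 1 else 1
    n_epochs = values.shape[0] // epoch_len
    if n_epochs == 0:
        raise ValueError("series shorter than one epoch")
    scores = np.empty((n_epochs, n_windows, len(PAIR_ORDER)))
    for e in range(n_epochs):
        epoch = values[e * epoch_len : (e + 1) * epoch_len]
        for w in range(n_windows):
            seg = epoch[w * step : w * step + window_len]
            for p, (i, j) in enumerate(PAIR_ORDER):
                if j > i:  # each unordered pair computed once, both directions
                    res = ccs(seg[:, i], seg[:, j], params, direction="both", **ccs_kwargs)
                    scores[e, w, PAIR_ORDER.index((i, j))] = res["x_to_y"].value
                    scores[e, w, PAIR_ORDER.index((j, i))] = res["y_to_x"].value
    return WindowedScores(scores, window_len, step, labels=labels)


def cluster_states(
    ws: WindowedScores, k: int = 5, seed: int | None = None, n_init: int = 10
) -> dict:
    """Quantize the 6-D score space into ``k`` network states with k-means.

    Scores are standardized and whitened (full-dimensional PCA) before
    clustering; the first two principal components serve display only —
    clustering runs in the full whitened space. Centroids are back-transformed
    to raw score units. Returns centroids, per-epoch state sequences, the
    per-window labels, the fitted transforms and the 2-D projection.
    """
    X = ws.flat
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of windows ({X.shape[0]})")
    scaler = StandardScaler().fit(X)
    pca = PCA(whiten=True, random_state=seed).fit(scaler.transform(X))
    Z = pca.transform(scaler.transform(X))
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Z)
    centroids = scaler.inverse_transform(pca.inverse_transform(km.cluster_centers_))
    sequences = km.labels_.reshape(ws.scores.shape[0], ws.scores.shape[1])
    return {
        "centroids": centroids,
        "sequences": sequences,
        "labels": km.labels_,
        "projection": Z[:, :2],
        "scaler": scaler,
        "pca": pca,
        "kmeans": km,
    }


def canonical_cycle(seq) -> tuple:
    """Lexicographically smallest cyclic rotation of a sequence."""
    seq = tuple(int(s) for s in seq)
    return min(seq[i:] + seq[:i] for i in range(len(seq)))


def n_canonical_sequences(k: int, length: int) -> int:
    """Number of distinct sequences of ``length`` symbols from ``k`` states
    up to cyclic rotation (necklace count, by Burnside's lemma)."""
    total = 0
    for d in range(1, length + 1):
        if length % d == 0:
            phi = sum(1 for m in range(1, d + 1) if gcd(m, d) == 1)
            total += phi * k ** (length // d)
    return total // length


def sequence_statistics(
    sequences: np.ndarray,
    conditions=None,
    n_states: int | None = None,
    top: int = 10,
    null: str = "order",
    n_null: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-condition frequency table of cyclic-canonical state sequences.

    Each epoch's sequence is canonicalized to its smallest cyclic rotation and
    tabulated. ``pct`` carries the binomial standard error of the percentage.
    ``neg_log10_p`` is the extremeness of the n-th most frequent pattern: the
    negative log10 of the probability that the n-th largest count under a
    uniform-over-canonical-sequences null would be at least as large as the
    one observed. The default ``null="order"`` estimates that order-statistic
    probability by seeded Monte Carlo over multinomial draws (a plain
    binomial tail, ``null="binomial"``, ignores the selection of the n-th
    most frequent pattern and overstates extremeness).
    """
    sequences = np.asarray(sequences, dtype=int)
    if sequences.ndim != 2:
        raise ValueError("sequences must be (n_epochs, n_windows)")
    if len(sequences) == 0:
        raise ValueError("no epochs to tabulate")
    if conditions is None:
        conditions = np.array(["all"] * len(sequences))
    conditions = np.asarray(conditions)
    n_states = int(n_states if n_states is not None else sequences.max() + 1)
    n_classes = n_canonical_sequences(n_states, sequences.shape[1])
    rng = np.random.default_rng(seed)
    rows = []
    for cond in pd.unique(conditions):
        mask = conditions == cond
        if not mask.any():
            raise ValueError(f"condition {cond!r} has no epochs")
        canon = [canonical_cycle(s) for s in sequences[mask]]
        n = len(canon)
        counts = pd.Series(canon).value_counts()
        if null == "order":
            sims = rng.multinomial(n, np.full(n_classes, 1.0 / n_classes), size=n_null)
            sims.sort(axis=1)
            order_counts = sims[:, ::-1]  # descending per draw
        for rank, (pattern, count) in enumerate(counts.head(top).items(), start=1):
            p = count / n
            se = 100 * np.sqrt(p * (1 - p) / n)
            if null == "order":
                tail = (1 + np.sum(order_counts[:, rank - 1] >= count)) / (1 + n_null)
            elif null == "binomial":
                tail = stats.binom.sf(count - 1, n, 1.0 / n_classes)
            else:
                raise ValueError(f"unknown null {null!r}")
            rows.append(
                {
                    "condition": cond,
                    "rank": rank,
                    "pattern": pattern,
                    "count": int(count),
                    "pct": 100 * p,
                    "pct_se": se,
                    "neg_log10_p": float(-np.log10(max(tail, 1e-300))),
                }
            )
    return pd.DataFrame(rows)
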