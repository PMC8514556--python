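"""Model-style front end: build a coupling model from multichannel data,
fit it, and inspect the directed score table.

Example
-------
>>> model = CouplingModel(values, labels=["x", "y", "z"], methods=("ccs", "ccm"))
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ccm import ccm
from .ccs import DEFAULT_MAX_RANK_FRAC, ccs, ccs_significance
from .embedding import EmbeddingParams, select_embedding_params
from .timeseries import TimeSeries

__all__ = ["CouplingModel", "CouplingResults"]


class CouplingModel:
    """Directed-coupling model over every ordered channel pair.

    Parameters
    ----------
    data : ndarray, TimeSeries or DataFrame
        Samples x channels.
    methods : sequence of {"ccs", "ccm"}
        Correspondence statistics to fit.
    dim, lag : int, optional
        Shared embedding parameters; selected automatically from the first
        channel when omitted (so that scores stay commensurable across pairs).
    exclusion_window : int, optional
        Theiler-style temporal exclusion; default ``dim * lag``.
    """

    def __init__(
        self,
        data,
        labels: Sequence[str] | None = None,
        methods: Sequence[str] = ("ccs",),
        dim: int | None = None,
        lag: int | None = None,
        exclusion_window: int | None = None,
        standardize: bool = True,
        max_rank_frac: float = DEFAULT_MAX_RANK_FRAC,
        null_mode: str = "conditional",
    ):
        if isinstance(data, TimeSeries):
            ts = data
        elif isinstance(data, pd.DataFrame):
            ts = TimeSeries(data.to_numpy(dtype=float), labels=list(data.columns))
        else:
            ts = TimeSeries(np.asarray(data, dtype=float), labels=list(labels) if labels else None)
        if labels is not None:
            ts.labels = list(labels)
        if ts.n_channels < 2:
            raise ValueError("need at least two channels to estimate coupling")
        self.data = ts
        self.methods = tuple(methods)
        for m in self.methods:
            if m not in ("ccs", "ccm"):
                raise ValueError(f"unknown method {m!r}")
        if dim is None or lag is None:
            L = len(ts)
            auto = select_embedding_params(
                ts.channel(0),
                max_dim=min(8, max(2, L // 25)),
                max_lag=min(50, max(2, L // 10)),
                dim=dim,
                lag=lag,
            )
            dim, lag = auto.dim, auto.lag
        self.params = EmbeddingParams(dim, lag)
        self.exclusion_window = (
            exclusion_window if exclusion_window is not None else dim * lag
        )
        self.standardize = standardize
        self.max_rank_frac = max_rank_frac
        self.null_mode = null_mode

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CouplingModel":
        return cls(df, **kwargs)

    def fit(self, surrogates: int = 0, seed: int | None = None) -> "CouplingResults":
        """Score every ordered channel pair; optional surrogate p-values (CCS)."""
        rows = []
        n = self.data.n_channels
        ccs_kw = dict(
            exclusion_window=self.exclusion_window,
            max_rank_frac=self.max_rank_frac,
            null_mode=self.null_mode,
            standardize=self.standardize,
        )
        for i in range(n):
            for j in range(i + 1, n):
                x, y = self.data.channel(i), self.data.channel(j)
                lab = (self.data.labels[i], self.data.labels[j])
                for m in self.methods:
                    if m == "ccs":
                        res = ccs(x, y, self.params, "both", labels=lab, **ccs_kw)
                    else:
                        res = ccm(
                            x, y, self.params, "both",
                            exclusion_window=self.exclusion_window,
                            standardize=self.standardize, labels=lab,
                        )
                    for d, sc in res.items():
                        p = None
                        if surrogates and m == "ccs":
                            _, p = ccs_significance(
                                x, y, self.params, d, surrogates,
                                seed=None if seed is None else seed + 97 * (i * n + j),
                                **ccs_kw,
                            )
                        rows.append(
                            {
                                "source": sc.source,
                                "target": sc.target,
                                "method": m,
                                "score": sc.value,
                                "p_value": p,
                                "fit_ok": sc.fit_ok,
                            }
                        )
        return CouplingResults(self, pd.DataFrame(rows))


@dataclass
class CouplingResults:
    """Fitted directed coupling scores with accessors and a summary table."""

    model: CouplingModel
    scores: pd.DataFrame = field(repr=False)

    def score_matrix(self, method: str | None = None) -> pd.DataFrame:
        """n x n DataFrame with entry (i, j) = score(i -> j)."""
        method = method or self.model.methods[0]
        labels = self.model.data.labels
        M = pd.DataFrame(0.0, index=labels, columns=labels)
        sub = self.scores[self.scores["method"] == method]
        for _, row in sub.iterrows():
            M.loc[row["source"], row["target"]] = row["score"]
        return M

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "Directed coupling estimates",
            "=" * 62,
            f"Channels: {', '.join(self.model.data.labels)}   "
            f"n_obs: {len(self.model.data)}",
            f"Embedding: dim={p.dim}, lag={p.lag}, "
            f"exclusion={self.model.exclusion_window}, "
            f"max_rank_frac={self.model.max_rank_frac}",
            "-" * 62,
            f"{'source':>8} {'target':>8} {'method':>7} {'score':>8} "
            f"{'p_value':>9} {'fit_ok':>7}",
        ]
        for _, r in self.scores.iterrows():
            pv = "-" if r["p_value"] is None or pd.isna(r["p_value"]) else f"{r['p_value']:.4g}"
            lines.append(
                f"{r['source']:>8} {r['target']:>8} {r['method']:>7} "
                f"{r['score']:>8.3f} {pv:>9} {str(bool(r['fit_ok'])):>7}"
            )
        lines.append("=" * 62)
        return "\n".join(lines)
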