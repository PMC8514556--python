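"""Uniformly sampled time-series container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeries:
    """Uniformly sampled scalar or multichannel observations.

    Parameters
    ----------
    values : ndarray
        Shape ``(L,)`` for a single channel or ``(L, C)`` for ``C`` channels.
    dt : float
        Sampling interval in arbitrary time units (default 1).
    labels : list of str, optional
        Channel names; autogenerated ``ch0, ch1, ...`` when omitted.
    """

    values: np.ndarray
    dt: float = 1.0
    labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (1, 2):
            raise ValueError("values must be 1-D (L,) or 2-D (L, C)")
        if len(self.values) < 2:
            raise ValueError("time series must contain at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.labels is None:
            self.labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.labels) != self.n_channels:
            raise ValueError("number of labels does not match number of channels")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    def channel(self, key: int | str) -> np.ndarray:
        """Return one channel as a 1-D array (by index or label)."""
        if isinstance(key, str):
            key = self.labels.index(key)
        if self.values.ndim == 1:
            if key != 0:
                raise IndexError("scalar series has a single channel 0")
            return self.values
        return self.values[:, key]


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sd 1; a constant channel is an error.

    Scoring methods compare distance scales across channels, so channels are
    standardized by default before embedding.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant channel")
    return (x - x.mean()) / sd
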