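"""Small seeded datasets exercising specific code paths (tests and docs)."""

from __future__ import annotations

import numpy as np

from .simulators import (
    NetworkSpec,
    NoiseSpec,
    TrialResult,
    make_topologies,
    simulate_logistic_map,
    simulate_vdp,
)
from .timeseries import TimeSeries

__all__ = ["make_fixture", "FIXTURE_TAGS"]

FIXTURE_TAGS = (
    "identical-pair",
    "independent-noise",
    "lm-unidirectional",
    "vdp-synchronous",
    "regime-switch-triad",
)


def _pair_result(values, spec, truth) -> TrialResult:
    ts = TimeSeries(values, labels=[f"v{i}" for i in range(values.shape[1])])
    return TrialResult(series=ts, spec=spec, noise=NoiseSpec(), truth=truth)


def make_fixture(name: str, seed: int = 0, L: int = 400) -> TrialResult:
    """Return a small, seeded, documented dataset for a known tag.

    Tags: ``identical-pair`` (two equal logistic-map channels),
    ``independent-noise`` (two independent white-noise channels),
    ``lm-unidirectional`` (x drives y, strong K), ``vdp-synchronous``
    (strong symmetric VDP coupling), ``regime-switch-triad`` (three VDP
    channels whose coupling schedule switches mid-epoch; the schedule lives
    in ``spec.system_params["schedule"]``).
    """
    rng = np.random.default_rng(seed)
    if name == "identical-pair":
        spec = NetworkSpec(1, np.zeros((1, 1)), "lm", {"r": [3.8]})
        x = simulate_logistic_map(spec, L, seed=seed).series.values
        vals = np.column_stack([x, x])
        pair = NetworkSpec(2, np.zeros((2, 2)), "lm", {"r": [3.8, 3.8]}, "identical")
        return _pair_result(vals, pair, np.zeros((2, 2), dtype=bool))
    if name == "independent-noise":
        vals = rng.standard_normal((L, 2))
        spec = NetworkSpec(2, np.zeros((2, 2)), "ar", {"a": [[0.0], [0.0]]}, "independent")
        return _pair_result(vals, spec, np.zeros((2, 2), dtype=bool))
    if name == "lm-unidirectional":
        (spec,) = make_topologies("two_var", K_pair=(0.35, 0.0), system="lm")
        return simulate_logistic_map(spec, L, seed=seed)
    if name == "vdp-synchronous":
        (spec,) = make_topologies("two_var", K_pair=(0.5, 0.5), system="vdp")
        return simulate_vdp(spec, L, seed=seed)
    if name == "regime-switch-triad":
        # two coupling regimes alternating every half epoch of 120 samples
        K_on = np.zeros((3, 3))
        K_on[0, 1] = K_on[0, 2] = 0.3
        schedule = [("off", np.zeros((3, 3))), ("driver_on", K_on)]
        seg_len = 60
        chunks = []
        for s in range(max(2, L // seg_len)):
            _, K = schedule[s % 2]
            spec = NetworkSpec(3, K, "lm", {}, "regime-switch")
            chunks.append(
                simulate_logistic_map(spec, seg_len, seed=seed + s).series.values
            )
        vals = np.vstack(chunks)
        spec = NetworkSpec(
            3,
            K_on,
            "lm",
            {"schedule": [(tag, K.tolist()) for tag, K in schedule], "seg_len": seg_len},
            "regime-switch-triad",
        )
        return _pair_result(vals, spec, K_on > 0)
    raise ValueError(f"unknown fixture tag {name!r}; known tags: {FIXTURE_TAGS}")
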