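"""Run configuration: a serializable record of every parameter and seed.

Every stochastic operation in the package takes an explicit seed; a RunConfig
plus the package version is sufficient to reproduce a run bit-for-bit on its
deterministic paths.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "write_manifest"]


@dataclass
class RunConfig:
    method: list[str] = field(default_factory=lambda: ["ccs"])
    dim: int | None = None
    lag: int | None = None
    exclusion_window: int | None = None
    max_rank_frac: float = 0.25
    null_mode: str = "conditional"
    standardize: bool = True
    surrogates: int = 0
    seed: int = 0
    system: str = "lm"
    topology: str = "three_var"
    K: float = 0.2
    L: int = 200
    snr_db: float = float("inf")
    dyn_eps: float = 0.0
    n_trials: int = 200
    epoch_len: int = 120
    window_len: int = 48
    k_states: int = 5
    output: str = "results"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def write_manifest(out_dir, config: dict, seed: int | None) -> Path:
    """Write a reproduction manifest (config + seed + package version)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clean = {
        k: (None if v is None else (float(v) if isinstance(v, float) else v))
        for k, v in config.items()
    }
    manifest = {"version": __version__, "seed": seed, "config": clean}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
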