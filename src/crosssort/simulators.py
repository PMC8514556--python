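"""Simulated validation systems: coupled Van der Pol oscillators, logistic
maps and autoregressive models on small directed networks, with measurement
and dynamical noise.

Three signal classes span the space of properties the scoring methods face:
Van der Pol oscillators (deterministic, continuous, approximately periodic),
logistic maps (deterministic, discrete, chaotic) and autoregressive models
(linear, stochastic). Coupling is parameterized by a nonnegative matrix
``K[i, j]`` giving the strength of the directed edge i -> j.

Noise comes in two orthogonal flavors: measurement noise, Gaussian noise
added to the final output series and scaled by an SNR in dB (RMS of signal
over RMS of noise), and dynamical noise of magnitude ``eps`` injected into
the evolving state itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "NetworkSpec",
    "NoiseSpec",
    "TrialResult",
    "simulate_logistic_map",
    "simulate_vdp",
    "simulate_ar",
    "add_measurement_noise",
    "make_topologies",
    "THREE_VAR_TOPOLOGIES",
]

#: Transitive-free three-variable templates (directed edge lists). All other
#: three-variable layouts contain transitive causal paths, which make
#: pairwise ground truth ambiguous, so they are refused for detection trials.
THREE_VAR_TOPOLOGIES = {
    "common_driver": [(2, 0), (2, 1)],  # Z -> X, Z -> Y
    "common_sink": [(0, 2), (1, 2)],  # X -> Z, Y -> Z
    "bidirectional_pair": [(0, 1), (1, 0)],  # X <-> Y, Z isolated
}

_TRANSITIVE_EXAMPLES = {"chain", "fan_out_chain", "fully_connected"}


@dataclass
class NetworkSpec:
    """Generating topology with coupling coefficients.

    ``coupling[i, j]`` is the strength K of the directed edge i -> j
    (zero diagonal).
    """

    n_vars: int
    coupling: np.ndarray
    system: str  # "vdp" | "lm" | "ar"
    system_params: dict[str, Any] = field(default_factory=dict)
    topology_tag: str = ""

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (self.n_vars, self.n_vars):
            raise ValueError("coupling matrix shape must be (n_vars, n_vars)")
        if np.any(self.coupling < 0):
            raise ValueError("coupling strengths must be nonnegative")
        if np.any(np.diag(self.coupling) != 0):
            raise ValueError("coupling matrix must have zero diagonal")

    @property
    def truth(self) -> np.ndarray:
        """Boolean matrix of true directed edges."""
        return self.coupling > 0


@dataclass
class NoiseSpec:
    """Measurement SNR in dB (np.inf for none) and dynamical-noise magnitude."""

    snr_db: float = np.inf
    dyn_eps: float = 0.0

    def __post_init__(self) -> None:
        if np.isnan(self.snr_db):
            raise ValueError("snr_db must be a real dB value (np.inf for no noise)")
        if self.dyn_eps < 0:
            raise ValueError("dyn_eps must be >= 0")


@dataclass
class TrialResult:
    """A simulated multichannel series with its generating spec and ground truth."""

    series: TimeSeries
    spec: NetworkSpec
    noise: NoiseSpec
    truth: np.ndarray


def add_measurement_noise(series: TimeSeries, snr_db: float, seed=None) -> TimeSeries:
    """Add per-channel Gaussian noise at the given SNR (dB, RMS ratio).

    Noise RMS = RMS(signal) / 10^(snr_db/20); ``snr_db = inf`` returns the
    input unchanged (0 dB means noise RMS equals signal RMS).
    """
    if np.isnan(snr_db):
        raise ValueError("snr_db must be a real dB value")
    if np.isinf(snr_db):
        return series
    rng = np.random.default_rng(seed)
    vals = np.atleast_2d(series.values.T).T.copy()
    for c in range(vals.shape[1]):
        rms = np.sqrt(np.mean(vals[:, c] ** 2))
        if rms == 0:
            raise ValueError(f"channel {c} has zero RMS; SNR undefined")
        vals[:, c] += rng.normal(0.0, rms / 10 ** (snr_db / 20.0), size=len(vals))
    if series.values.ndim == 1:
        vals = vals[:, 0]
    return TimeSeries(vals, dt=series.dt, labels=list(series.labels))


def _finish(raw: np.ndarray, spec, noise, rng, dt=1.0) -> TrialResult:
    ts = TimeSeries(raw, dt=dt, labels=[f"v{i}" for i in range(spec.n_vars)])
    ts = add_measurement_noise(ts, noise.snr_db, seed=rng.integers(2**31))
    return TrialResult(series=ts, spec=spec, noise=noise, truth=spec.truth)


def simulate_logistic_map(
    spec: NetworkSpec,
    L: int,
    noise: NoiseSpec | None = None,
    seed=None,
    burn_in: int = 500,
    max_retries: int = 20,
) -> TrialResult:
    """Coupled logistic maps on the unit interval.

    Update: ``x_i(t+1) = x_i(t) * [r_i - r_i*x_i(t) - sum_j K[j->i]*x_j(t)]``
    plus additive dynamical noise of sd ``eps``, clipped back into (0, 1).
    Intrinsic rates ``r`` come from ``spec.system_params["r"]`` (default
    drawn uniformly from the chaotic band (3.6, 3.9)); optional fixed
    initial conditions via ``system_params["x0"]``. A deterministic
    trajectory that escapes (0, 1) is resampled from new initial conditions
    (bounded retries).
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    n = spec.n_vars
    r = np.asarray(
        spec.system_params.get("r", rng.uniform(3.6, 3.9, size=n)), dtype=float
    ) * np.ones(n)
    K = spec.coupling
    eps = noise.dyn_eps
    for _ in range(max_retries):
        x = np.asarray(
            spec.system_params.get("x0", rng.uniform(0.2, 0.8, size=n)), dtype=float
        ) * np.ones(n)
        out = np.empty((L, n))
        ok = True
        for t in range(burn_in + L):
            x_new = x * (r - r * x - K.T @ x)
            if eps > 0:
                x_new = x_new + eps * rng.standard_normal(n)
            if not np.all(np.isfinite(x_new)):
                ok = False
                break
            # coupling (or noise) can push the state out of the unit
            # interval; clip back so the map stays defined
            x = np.clip(x_new, 1e-9, 1 - 1e-9)
            if t >= burn_in:
                out[t - burn_in] = x
        if ok:
            return _finish(out, spec, noise, rng)
        if "x0" in spec.system_params:
            raise RuntimeError(
                f"logistic-map trajectory diverged for fixed x0 with r={r}, K=\n{K}"
            )
    raise RuntimeError(
        f"logistic-map simulation diverged after {max_retries} retries (r={r}, K max "
        f"{K.max():.3f}); reduce coupling or intrinsic rates"
    )


def _vdp_deriv(state: np.ndarray, mu: np.ndarray, K: np.ndarray) -> np.ndarray:
    x, v = state
    drive = K.T @ x - K.sum(axis=0) * x  # diffusive: sum_j K[j->i]*(x_j - x_i)
    return np.stack([v, mu * (1 - x**2) * v - x + drive])


def _vdp_deriv_direct(state: np.ndarray, mu: np.ndarray, K: np.ndarray) -> np.ndarray:
    x, v = state
    return np.stack([v, mu * (1 - x**2) * v - x + K.T @ x])


def simulate_vdp(
    spec: NetworkSpec,
    L: int,
    noise: NoiseSpec | None = None,
    seed=None,
    dt_int: float = 0.05,
    sample_every: int = 10,
    burn_in_periods: float = 50.0,
) -> TrialResult:
    """Coupled Van der Pol oscillators, fixed-step RK4.

    ``x''_i = mu_i (1 - x_i^2) x'_i - x_i + sum_j K[j->i] (x_j - x_i)``
    (diffusive coupling; direct forcing ``+ sum_j K[j->i] x_j`` available via
    ``system_params["coupling_form"] = "direct"``). Dynamical noise of
    magnitude ``eps`` is added to the velocity each step scaled by
    ``sqrt(dt_int)`` so its effect is step-size independent. The observed
    variable is the position, downsampled by ``sample_every``; a burn-in of
    ``burn_in_periods`` nominal periods (~6.66 time units each) is discarded.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    n = spec.n_vars
    mu = np.asarray(
        spec.system_params.get("mu", rng.uniform(0.8, 2.5, size=n)), dtype=float
    ) * np.ones(n)
    if np.any(mu <= 0):
        raise ValueError("VDP stiffness mu must be positive")
    deriv = (
        _vdp_deriv_direct
        if spec.system_params.get("coupling_form", "diffusive") == "direct"
        else _vdp_deriv
    )
    K = spec.coupling
    eps = noise.dyn_eps
    state = np.stack(
        [
            np.asarray(spec.system_params.get("x0", rng.uniform(-2, 2, size=n))) * np.ones(n),
            np.asarray(spec.system_params.get("v0", rng.uniform(-2, 2, size=n))) * np.ones(n),
        ]
    ).astype(float)
    burn_steps = int(round(burn_in_periods * 6.66 / dt_int))
    total = burn_steps + L * sample_every
    out = np.empty((L, n))
    sq = np.sqrt(dt_int)
    for step in range(total):
        k1 = deriv(state, mu, K)
        k2 = deriv(state + 0.5 * dt_int * k1, mu, K)
        k3 = deriv(state + 0.5 * dt_int * k2, mu, K)
        k4 = deriv(state + dt_int * k3, mu, K)
        state = state + (dt_int / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if eps > 0:
            state[1] += eps * sq * rng.standard_normal(n)
        if not np.all(np.isfinite(state)):
            raise RuntimeError("VDP integration produced non-finite state")
        k = step - burn_steps
        if k >= 0 and (k + 1) % sample_every == 0:
            out[(k + 1) // sample_every - 1] = state[0]
    return _finish(out, spec, noise, rng, dt=dt_int * sample_every)


def simulate_ar(
    spec: NetworkSpec,
    L: int,
    noise: NoiseSpec | None = None,
    seed=None,
    burn_in: int = 500,
) -> TrialResult:
    """Coupled stable autoregressive processes.

    ``x_i(t) = sum_p a_{i,p} x_i(t-p) + sum_j K[j->i] x_j(t-1) + e_i(t)``
    with Gaussian innovations of sd ``eps`` (the innovations ARE the
    dynamical stochasticity; ``eps`` defaults to 1 when unset since an AR
    process without innovations decays to zero). Intrinsic coefficients from
    ``system_params["a"]`` (per-variable lists; default AR(1) with a ~
    U(0.3, 0.9)). The joint lag-1 companion matrix must be stable.
    """
    noise = noise or NoiseSpec(dyn_eps=1.0)
    rng = np.random.default_rng(seed)
    n = spec.n_vars
    a = spec.system_params.get("a")
    if a is None:
        a = [[float(v)] for v in rng.uniform(0.3, 0.9, size=n)]
    a = [np.atleast_1d(np.asarray(ai, dtype=float)) for ai in a]
    p_max = max(len(ai) for ai in a)
    # companion matrix of the joint system (coupling acts at lag 1)
    comp = np.zeros((n * p_max, n * p_max))
    for i in range(n):
        for p, coef in enumerate(a[i]):
            comp[i, p * n + i] = coef
    comp[:n, :n] += spec.coupling.T * (np.eye(n) == 0)
    if p_max > 1:
        comp[n:, :-n] = np.eye(n * (p_max - 1))
    radius = np.max(np.abs(np.linalg.eigvals(comp)))
    if radius >= 1:
        raise ValueError(
            f"joint AR system unstable (spectral radius {radius:.3f} >= 1)"
        )
    eps = noise.dyn_eps if noise.dyn_eps > 0 else 1.0
    hist = np.zeros((p_max, n))
    out = np.empty((L, n))
    for t in range(burn_in + L):
        new = np.zeros(n)
        for i in range(n):
            for p, coef in enumerate(a[i]):
                new[i] += coef * hist[p, i]
        new += spec.coupling.T @ hist[0]
        new += eps * rng.standard_normal(n)
        hist = np.vstack([new, hist[:-1]])
        if t >= burn_in:
            out[t - burn_in] = new
    return _finish(out, spec, noise, rng)


def make_topologies(
    kind: str,
    K: float | None = None,
    K_pair: tuple[float, float] | None = None,
    system: str = "lm",
    system_params: dict | None = None,
) -> list[NetworkSpec]:
    """Build the template networks used by the validation experiments.

    ``kind="three_var"`` emits every transitive-free three-variable template
    with both edges at the shared strength ``K``; ``kind="two_var"`` emits the
    bidirectional pair with independent ``K_pair = (K_xy, K_yx)``. Requesting
    a known transitive topology raises.
    """
    if kind in _TRANSITIVE_EXAMPLES:
        raise ValueError(
            f"topology {kind!r} contains transitive causal relationships, which make "
            "pairwise ground truth ambiguous; use a transitive-free template"
        )
    system_params = dict(system_params or {})
    if kind == "three_var":
        if K is None or K < 0:
            raise ValueError("three_var templates require a shared K >= 0")
        specs = []
        for tag, edges in THREE_VAR_TOPOLOGIES.items():
            C = np.zeros((3, 3))
            for i, j in edges:
                C[i, j] = K
            specs.append(
                NetworkSpec(3, C, system, dict(system_params), topology_tag=tag)
            )
        return specs
    if kind == "two_var":
        if K_pair is None:
            raise ValueError("two_var template requires K_pair=(K_xy, K_yx)")
        kxy, kyx = K_pair
        if kxy < 0 or kyx < 0:
            raise ValueError("coupling strengths must be >= 0")
        C = np.array([[0.0, kxy], [kyx, 0.0]])
        return [NetworkSpec(2, C, system, dict(system_params), topology_tag="pair")]
    raise ValueError(f"unknown topology kind {kind!r}")


_SIMULATORS = {
    "lm": simulate_logistic_map,
    "vdp": simulate_vdp,
    "ar": simulate_ar,
}


def simulate(spec: NetworkSpec, L: int, noise=None, seed=None, **kwargs) -> TrialResult:
    """Dispatch to the simulator named by ``spec.system``."""
    try:
        fn = _SIMULATORS[spec.system]
    except KeyError:
        raise ValueError(f"unknown system {spec.system!r}") from None
    return fn(spec, L, noise, seed, **kwargs)
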