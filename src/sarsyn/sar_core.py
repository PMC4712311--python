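"""Forward simulation of the synchronous-asynchronous release (SAR) synapse model.

The SAR model extends the Tsodyks-Markram short-term-plasticity description of
synchronous vesicle release with a second, slower Ca2+-sensor pathway that
releases vesicles *asynchronously*, i.e. not time-locked to presynaptic spikes.
Both pathways compete for a single readily-releasable pool.

State variables
---------------
u_sr : synchronous release probability (dimensionless, in [0, 1]).
       Jumps by ``U_sr * (1 - u_sr)`` at each spike, decays with ``tau_sr``.
u_ar : asynchronous release probability *rate* (1/ms, in [U0, U_max]).
       Jumps by ``U_ar * (U_max - u_ar)`` at each spike, decays with ``tau_ar``
       towards the spontaneous floor ``U0`` (0 by default).
N / x : available resources. Stochastic mode tracks the integer vesicle count
       ``N`` in {0..N_F}; deterministic (mean-field) mode tracks the continuous
       transmitter amount ``x`` in [0, X_F], X_F = N_F * x0.

Stochastic mode draws, per time bin of width dt:

* in a spike bin, ``n_sr ~ Binomial(N, u_sr(t+))`` synchronously released
  vesicles (from the pre-spike pool, with the post-spike probability),
* ``n_ar ~ Binomial(N - n_sr, u_ar * dt)`` asynchronously released vesicles,
* ``r ~ Binomial(N_F - N, dt / tau_d)`` replenished vesicles,

and updates ``N <- N - n_sr - n_ar + r``.  Released transmitter per bin is
``x0 * n``.  Drawing the asynchronous count from the post-synchronous pool
guarantees ``N >= 0`` without rejection sampling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SARParams",
    "SynapseState",
    "ReleaseTrace",
    "ReleaseEnsemble",
    "snap_spikes",
    "decay",
    "on_spike_facilitation",
    "draw_release_and_replenish",
    "simulate",
    "simulate_trials",
]

#: default simulation bin width (ms); matches the sampling of the voltage-clamp
#: recordings the inverse pipeline targets.
DEFAULT_DT = 0.05

#: default transmission delay (ms) between presynaptic spike and postsynaptic
#: current onset.
DEFAULT_DELAY = 0.75


@dataclass(frozen=True)
class SARParams:
    """Full SAR parameter vector plus structural constants.

    Time constants in ms, increments dimensionless, ``U_max``/``U0`` in 1/ms.
    ``N_F`` is the maximal vesicle count, ``x0`` the transmitter content of a
    single vesicle (quantum size), ``D`` the transmission delay in ms.
    """

    tau_sr: float
    U_sr: float
    tau_ar: float
    U_ar: float
    U_max: float
    tau_d: float
    N_F: int = 271
    x0: float = 1.0
    U0: float = 0.0
    D: float = DEFAULT_DELAY

    def __post_init__(self) -> None:
        for name in ("tau_sr", "tau_ar", "tau_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.U_sr <= 1.0:
            raise ValueError("U_sr must lie in [0, 1]")
        if not 0.0 <= self.U_ar <= 1.0:
            raise ValueError("U_ar must lie in [0, 1]")
        if self.U_max <= 0:
            raise ValueError("U_max must be positive")
        if not 0.0 <= self.U0 <= self.U_max:
            raise ValueError("U0 must lie in [0, U_max]")
        if self.N_F < 1 or int(self.N_F) != self.N_F:
            raise ValueError("N_F must be a positive integer")
        if self.x0 <= 0:
            raise ValueError("x0 must be positive")

    @property
    def X_F(self) -> float:
        """Total transmitter amount when the pool is full."""
        return self.N_F * self.x0

    def to_dict(self) -> dict:
        return {
            "tau_sr": self.tau_sr, "U_sr": self.U_sr,
            "tau_ar": self.tau_ar, "U_ar": self.U_ar,
            "U_max": self.U_max, "tau_d": self.tau_d,
            "N_F": int(self.N_F), "x0": self.x0,
            "U0": self.U0, "D": self.D,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SARParams":
        d = dict(d)
        d.setdefault("U0", 0.0)
        d.setdefault("D", DEFAULT_DELAY)
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SARParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SynapseState:
    """Instantaneous synapse state.

    Either ``N`` (stochastic vesicle count) or ``x`` (deterministic transmitter
    amount) is tracked, depending on the simulation mode.
    """

    u_sr: float = 0.0
    u_ar: float = 0.0
    N: int | None = None
    x: float | None = None

    @classmethod
    def rest(cls, params: SARParams, mode: str = "stochastic") -> "SynapseState":
        if mode == "stochastic":
            return cls(u_sr=0.0, u_ar=params.U0, N=int(params.N_F))
        return cls(u_sr=0.0, u_ar=params.U0, x=params.X_F)


@dataclass
class ReleaseTrace:
    """Time-binned record of a single simulated trial.

    ``q_sr``/``q_ar`` are per-bin released transmitter *amounts* (x0 per
    vesicle); a rate is obtained by dividing by ``dt``.  Stochastic traces also
    carry integer vesicle counts and the pool history ``N`` (value at bin
    start); deterministic traces carry the continuous resource ``x`` instead.
    ``u_sr``/``u_ar`` are post-facilitation values at each bin.
    """

    dt: float
    t0: float
    q_sr: np.ndarray
    q_ar: np.ndarray
    u_sr: np.ndarray
    u_ar: np.ndarray
    mode: str
    n_sr: np.ndarray | None = None
    n_ar: np.ndarray | None = None
    r: np.ndarray | None = None
    N: np.ndarray | None = None
    x: np.ndarray | None = None
    spike_bins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.q_sr))

    @property
    def q_total(self) -> np.ndarray:
        return self.q_sr + self.q_ar


@dataclass
class ReleaseEnsemble:
    """Stacked stochastic trials (shape ``(n_trials, n_bins)`` per array).

    ``u_sr``/``u_ar`` are shared across trials (their dynamics carry no noise).
    """

    dt: float
    t0: float
    q_sr: np.ndarray
    q_ar: np.ndarray
    n_sr: np.ndarray
    n_ar: np.ndarray
    r: np.ndarray
    N: np.ndarray
    u_sr: np.ndarray
    u_ar: np.ndarray
    spike_bins: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.q_sr.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.q_sr.shape[1])

    def trial(self, i: int) -> ReleaseTrace:
        return ReleaseTrace(
            dt=self.dt, t0=self.t0, q_sr=self.q_sr[i], q_ar=self.q_ar[i],
            u_sr=self.u_sr, u_ar=self.u_ar, mode="stochastic",
            n_sr=self.n_sr[i], n_ar=self.n_ar[i], r=self.r[i], N=self.N[i],
            spike_bins=self.spike_bins,
        )


def snap_spikes(spikes: Sequence[float], dt: float, n_bins: int) -> np.ndarray:
    """Snap spike times to the nearest grid bin; returns sorted bin indices.

    Raises if spikes are unsorted, fall outside ``[0, n_bins*dt)``, or would
    need to move by more than ``dt/2`` (cannot be represented on the grid).
    """
    t = np.asarray(spikes, dtype=float)
    if t.size == 0:
        return np.empty(0, dtype=int)
    if np.any(np.diff(t) <= 0):
        raise ValueError("spike times must be strictly increasing")
    idx = np.rint(t / dt).astype(int)
    if np.any(np.abs(t - idx * dt) > dt / 2 + 1e-9 * dt):
        raise ValueError("spike time cannot be snapped to the grid (off by > dt/2)")
    if np.any(idx < 0) or np.any(idx >= n_bins):
        raise ValueError("spike outside the simulation interval [0, T)")
    if np.any(np.diff(idx) == 0):
        raise ValueError("two spikes snapped to the same bin; decrease dt")
    return idx


def decay(state: SynapseState, dt: float, params: SARParams) -> SynapseState:
    """Relax the release probabilities over ``dt`` (exact exponentials).

    ``u_sr`` decays to 0 with ``tau_sr``; ``u_ar`` decays to the spontaneous
    floor ``U0`` with ``tau_ar``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u_sr = state.u_sr * math.exp(-dt / params.tau_sr)
    u_ar = params.U0 + (state.u_ar - params.U0) * math.exp(-dt / params.tau_ar)
    return replace(state, u_sr=u_sr, u_ar=u_ar)


def on_spike_facilitation(state: SynapseState, params: SARParams) -> SynapseState:
    """Apply the spike-triggered facilitation jumps (gives u(t+))."""
    u_sr = state.u_sr + params.U_sr * (1.0 - state.u_sr)
    u_ar = state.u_ar + params.U_ar * (params.U_max - state.u_ar)
    return replace(state, u_sr=u_sr, u_ar=u_ar)


def _check_dt(params: SARParams, dt: float) -> None:
    if params.U_max * dt > 1.0:
        raise ValueError("U_max * dt > 1: asynchronous release probability per bin invalid")
    if dt / params.tau_d > 1.0:
        raise ValueError("dt / tau_d > 1: replenishment probability per bin invalid")


def draw_release_and_replenish(
    state: SynapseState,
    is_spike_bin: bool,
    dt: float,
    params: SARParams,
    rng: np.random.Generator,
) -> tuple[SynapseState, int, int, int]:
    """One stochastic release/replenishment step on the vesicle pool.

    In a spike bin the synchronous draw comes first (from the full pre-spike
    pool, with probability ``u_sr(t+)``), then the asynchronous draw from the
    remaining vesicles; replenishment is drawn every bin.
    """
    _check_dt(params, dt)
    N = state.N
    if N is None:
        raise ValueError("stochastic step requires an integer pool count N")
    n_sr = int(rng.binomial(N, state.u_sr)) if is_spike_bin else 0
    n_ar = int(rng.binomial(N - n_sr, state.u_ar * dt))
    r = int(rng.binomial(params.N_F - N, dt / params.tau_d))
    N_new = N - n_sr - n_ar + r
    return replace(state, N=N_new), n_sr, n_ar, r


def _resource_step(x: float, u_ar: float, dt: float, params: SARParams) -> float:
    # dx/dt = (X_F - x)/tau_d - x*u_ar with u_ar frozen over the bin:
    # exponential relaxation towards X_F/(tau_d*a) with rate a = 1/tau_d + u_ar.
    a = 1.0 / params.tau_d + u_ar
    x_inf = params.X_F / (params.tau_d * a)
    return x_inf + (x - x_inf) * math.exp(-a * dt)


def simulate(
    params: SARParams,
    spikes: Sequence[float],
    T: float,
    dt: float = DEFAULT_DT,
    mode: Literal["stochastic", "deterministic"] = "stochastic",
    seed: int | np.random.Generator | None = None,
) -> ReleaseTrace:
    """Simulate one trial of the SAR model on a fixed time grid.

    Per-bin event order at spike bins: facilitation jumps (giving u(t+)),
    synchronous release from the pre-spike pool, asynchronous release from the
    remainder, replenishment, then exponential decay of u over dt.

    Parameters
    ----------
    spikes : sorted spike times in ms within [0, T); snapped to the grid.
    T : simulated duration (ms); the trace has ``ceil(T/dt)`` bins.
    mode : "stochastic" draws binomial vesicle counts; "deterministic" runs the
        mean-field model on the continuous resource x.
    seed : int seed or a ``numpy.random.Generator`` (stochastic mode only).
    """
    _check_dt(params, dt)
    n_bins = int(math.ceil(T / dt))
    spike_bins = snap_spikes(spikes, dt, n_bins)
    is_spike = np.zeros(n_bins, dtype=bool)
    is_spike[spike_bins] = True

    q_sr = np.zeros(n_bins)
    q_ar = np.zeros(n_bins)
    u_sr_h = np.zeros(n_bins)
    u_ar_h = np.zeros(n_bins)

    if mode == "stochastic":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        state = SynapseState.rest(params, "stochastic")
        n_sr_h = np.zeros(n_bins, dtype=np.int64)
        n_ar_h = np.zeros(n_bins, dtype=np.int64)
        r_h = np.zeros(n_bins, dtype=np.int64)
        N_h = np.zeros(n_bins, dtype=np.int64)
        for i in range(n_bins):
            N_h[i] = state.N
            if is_spike[i]:
                state = on_spike_facilitation(state, params)
            u_sr_h[i], u_ar_h[i] = state.u_sr, state.u_ar
            state, n_sr, n_ar, r = draw_release_and_replenish(
                state, bool(is_spike[i]), dt, params, rng
            )
            n_sr_h[i], n_ar_h[i], r_h[i] = n_sr, n_ar, r
            q_sr[i] = params.x0 * n_sr
            q_ar[i] = params.x0 * n_ar
            state = decay(state, dt, params)
        return ReleaseTrace(
            dt=dt, t0=0.0, q_sr=q_sr, q_ar=q_ar, u_sr=u_sr_h, u_ar=u_ar_h,
            mode=mode, n_sr=n_sr_h, n_ar=n_ar_h, r=r_h, N=N_h,
            spike_bins=spike_bins,
        )

    if mode != "deterministic":
        raise ValueError(f"unknown mode: {mode!r}")

    state = SynapseState.rest(params, "deterministic")
    x_h = np.zeros(n_bins)
    for i in range(n_bins):
        x_h[i] = state.x
        if is_spike[i]:
            state = on_spike_facilitation(state, params)
            q_sr[i] = state.u_sr * state.x  # u_sr(t+) * x(t-)
            state = replace(state, x=state.x - q_sr[i])
        u_sr_h[i], u_ar_h[i] = state.u_sr, state.u_ar
        q_ar[i] = state.x * state.u_ar * dt
        state = replace(state, x=_resource_step(state.x, state.u_ar, dt, params))
        state = decay(state, dt, params)
    return ReleaseTrace(
        dt=dt, t0=0.0, q_sr=q_sr, q_ar=q_ar, u_sr=u_sr_h, u_ar=u_ar_h,
        mode=mode, x=x_h, spike_bins=spike_bins,
    )


def release_probabilities(
    params: SARParams, spike_bins: np.ndarray, n_bins: int, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic post-facilitation u_sr/u_ar time courses (no noise)."""
    u_sr = np.zeros(n_bins)
    u_ar = np.zeros(n_bins)
    f_sr = math.exp(-dt / params.tau_sr)
    f_ar = math.exp(-dt / params.tau_ar)
    is_spike = np.zeros(n_bins, dtype=bool)
    is_spike[spike_bins] = True
    us, ua = 0.0, params.U0
    for i in range(n_bins):
        if is_spike[i]:
            us = us + params.U_sr * (1.0 - us)
            ua = ua + params.U_ar * (params.U_max - ua)
        u_sr[i], u_ar[i] = us, ua
        us *= f_sr
        ua = params.U0 + (ua - params.U0) * f_ar
    return u_sr, u_ar


def simulate_trials(
    params: SARParams,
    spikes: Sequence[float],
    T: float,
    dt: float = DEFAULT_DT,
    n_trials: int = 1,
    seed: int | np.random.Generator | None = None,
) -> ReleaseEnsemble:
    """Vectorised stochastic simulation of many independent trials.

    The release-probability dynamics are deterministic and shared across
    trials; only the binomial pool draws differ.  Equivalent in distribution
    to ``n_trials`` calls of :func:`simulate` (but drawn jointly, bin by bin).
    """
    _check_dt(params, dt)
    n_bins = int(math.ceil(T / dt))
    spike_bins = snap_spikes(spikes, dt, n_bins)
    u_sr, u_ar = release_probabilities(params, spike_bins, n_bins, dt)
    is_spike = np.zeros(n_bins, dtype=bool)
    is_spike[spike_bins] = True

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = np.full(n_trials, int(params.N_F), dtype=np.int64)
    n_sr = np.zeros((n_trials, n_bins), dtype=np.int64)
    n_ar = np.zeros((n_trials, n_bins), dtype=np.int64)
    r = np.zeros((n_trials, n_bins), dtype=np.int64)
    N_h = np.zeros((n_trials, n_bins), dtype=np.int64)
    p_rep = dt / params.tau_d
    for i in range(n_bins):
        N_h[:, i] = N
        if is_spike[i]:
            n_sr[:, i] = rng.binomial(N, u_sr[i])
        n_ar[:, i] = rng.binomial(N - n_sr[:, i], u_ar[i] * dt)
        r[:, i] = rng.binomial(params.N_F - N, p_rep)
        N = N - n_sr[:, i] - n_ar[:, i] + r[:, i]
    return ReleaseEnsemble(
        dt=dt, t0=0.0,
        q_sr=params.x0 * n_sr.astype(float),
        q_ar=params.x0 * n_ar.astype(float),
        n_sr=n_sr, n_ar=n_ar, r=r, N=N_h,
        u_sr=u_sr, u_ar=u_ar, spike_bins=spike_bins,
    )
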