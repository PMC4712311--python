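"""Forward model from transmitter release to postsynaptic current.

Under voltage clamp the receptor conductance translates into current through a
constant lumped gain ``A = w * (v - E_rev)``, so the synaptic current is the
convolution of the release rate with a single-exponential kernel
``K(s) = A * exp(-s / tau_syn)`` delayed by the transmission delay ``D``.

All computations here operate on release *magnitudes* and a positive gain; the
inhibitory (negative-going) sign of an IPSC is applied only at I/O time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .sar_core import DEFAULT_DELAY, ReleaseTrace

__all__ = ["ReceptorKernel", "CurrentTrace", "release_to_current", "split_currents"]


@dataclass(frozen=True)
class ReceptorKernel:
    """Exponential receptor kernel.

    tau_syn : conductance decay constant in ms (tau_GABA for GABA-A synapses;
        about 5 ms for fast-spiking -> pyramidal connections).
    A : lumped gain, current per transmitter unit (pA per unit); with quantum
        size x0 the single-vesicle IPSC amplitude is ``A * x0``.
    D : transmission delay in ms, snapped to the simulation grid.
    """

    tau_syn: float = 5.0
    A: float = 1.0
    D: float = DEFAULT_DELAY

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be strictly positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"tau_syn_ms": self.tau_syn, "A": self.A, "D_ms": self.D}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ReceptorKernel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tau_syn=d["tau_syn_ms"], A=d.get("A", 1.0), D=d.get("D_ms", DEFAULT_DELAY))


@dataclass
class CurrentTrace:
    """Uniformly sampled current trace (pA).

    ``kind`` distinguishes raw recordings (leak + negative IPSC + noise),
    leak-corrected traces, model reconstructions, and single release-pathway
    components.
    """

    dt: float
    t0: float
    I: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, dtype=float)
        if not np.all(np.isfinite(self.I)):
            raise ValueError("current trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.I))


def _delay_bins(D: float, dt: float) -> int:
    nd = int(round(D / dt))
    if abs(nd * dt - D) > dt / 2 + 1e-9 * dt:
        raise ValueError("delay D cannot be snapped to the grid")
    return nd


def release_to_current(
    q: np.ndarray | ReleaseTrace,
    kernel: ReceptorKernel,
    dt: float | None = None,
    t0: float = 0.0,
) -> CurrentTrace:
    """Convolve per-bin release amounts with the exponential receptor kernel.

    Implemented as the exact one-pole recursion
    ``I(i) = I(i-1) * exp(-dt/tau_syn) + A * q(i - D/dt)``
    (``q`` holds amounts = rate*dt), identical to the full convolution sum.
    Returns the current magnitude; the IPSC sign convention is applied at I/O.
    """
    if isinstance(q, ReleaseTrace):
        if dt is not None and abs(dt - q.dt) > 1e-12:
            raise ValueError("dt argument disagrees with the release trace's dt")
        dt, t0 = q.dt, q.t0
        q = q.q_total
    if dt is None:
        raise ValueError("dt required when q is a bare array")
    q = np.asarray(q, dtype=float)
    nd = _delay_bins(kernel.D, dt)
    q_delayed = np.zeros_like(q)
    if nd < len(q):
        q_delayed[nd:] = q[: len(q) - nd] if nd > 0 else q
    decay = math.exp(-dt / kernel.tau_syn)
    I = lfilter([kernel.A], [1.0, -decay], q_delayed)
    return CurrentTrace(dt=dt, t0=t0, I=I, kind="reconstructed")


def split_currents(
    trace: ReleaseTrace, kernel: ReceptorKernel
) -> tuple[CurrentTrace, CurrentTrace, CurrentTrace]:
    """Total, synchronous and asynchronous current components.

    By linearity of the kernel, ``I_total = I_sr + I_ar`` bin-wise.
    """
    I_sr = release_to_current(trace.q_sr, kernel, dt=trace.dt, t0=trace.t0)
    I_ar = release_to_current(trace.q_ar, kernel, dt=trace.dt, t0=trace.t0)
    I_sr.kind = I_ar.kind = "component"
    total = CurrentTrace(dt=trace.dt, t0=trace.t0, I=I_sr.I + I_ar.I, kind="reconstructed")
    return total, I_sr, I_ar
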