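"""Recovering the scaled release rate from a recorded postsynaptic current.

The pipeline is: subtract the leak current estimated from a pre-train baseline,
estimate the receptor kernel's decay constant from an isolated event, then run
a sequential constrained deconvolution that walks the trace bin by bin.  Since
the gain ``A`` and the release rate ``q`` only ever appear as a product in the
current, the deconvolution returns the *scaled* rate ``q~ = A*q`` (pA/ms); a
single released quantum contributes ``q~*dt = A*x0`` pA of instantaneous
current.

The deconvolution is deliberately not a Fourier/Wiener method: release events
are sparse and non-negative, and the constraint used here — the exponential
decay of everything asserted so far may never exceed the measured future trace
— keeps the estimate causal, non-negative and free of ringing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter1d
from scipy.optimize import curve_fit

from .receptor import CurrentTrace, ReceptorKernel

__all__ = [
    "ScaledReleaseTrace",
    "KernelFit",
    "subtract_leak",
    "fit_kernel",
    "deconvolve",
    "estimate_delay",
]

#: positivity clamp for the leak-corrected IPSC magnitude (pA): samples that
#: come out above -EPS_PA after leak subtraction are set to -EPS_PA.
EPS_PA = 0.2


@dataclass
class ScaledReleaseTrace:
    """Scaled release rate ``q~ = A*q`` on a uniform grid (pA/ms)."""

    dt: float
    t0: float
    q: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.q))


def subtract_leak(
    raw: CurrentTrace,
    baseline_window: tuple[float, float],
    eps: float = EPS_PA,
) -> CurrentTrace:
    """Subtract the mean baseline current and clamp to strictly negative values.

    ``baseline_window`` is a (start, end) interval in ms that must precede the
    first stimulus and contain at least 20 samples.  Any sample above ``-eps``
    after subtraction (noise excursions; the synaptic current of an inhibitory
    synapse is non-positive) is set to ``-eps``.
    """
    t = raw.times
    mask = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    if mask.sum() < 20:
        raise ValueError("baseline window must contain at least 20 samples")
    leak = float(raw.I[mask].mean())
    I = raw.I - leak
    I = np.minimum(I, -eps)
    return CurrentTrace(dt=raw.dt, t0=raw.t0, I=I, kind="leak_corrected")


@dataclass
class KernelFit:
    """Exponential-with-offset fit ``|I(t)| = a*exp(-t/tau) + b`` of one event."""

    tau_syn: float
    amplitude: float
    offset: float
    tau_ci: tuple[float, float]
    residual_norm: float
    in_range: bool

    def kernel(self, A: float = 1.0, D: float = 0.0) -> ReceptorKernel:
        return ReceptorKernel(tau_syn=self.tau_syn, A=A, D=D)


def fit_kernel(event: CurrentTrace, tau_range: tuple[float, float] = (0.1, 100.0)) -> KernelFit:
    """Estimate the receptor decay constant from a single event's falling phase.

    ``event`` must start at or after the event peak (e.g. a spontaneous
    miniature IPSC or a single-spike response).  Least squares on the current
    magnitude; the confidence interval is +/-1.96 SE from the fit covariance.
    A ``tau_syn`` outside ``tau_range`` is flagged via ``in_range=False``.
    """
    y = np.abs(event.I)
    t = event.times - event.t0

    def model(t, a, tau, b):
        return a * np.exp(-t / tau) + b

    a0 = max(y[0] - y[-1], 1e-6)
    tau0 = max((t[-1] - t[0]) / 3.0, event.dt)
    try:
        popt, pcov = curve_fit(
            model, t, y, p0=(a0, tau0, y[-1]),
            bounds=([0.0, 1e-3, -np.inf], [np.inf, 1e4, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise RuntimeError(f"kernel fit did not converge: {exc}") from exc
    a, tau, b = popt
    se = math.sqrt(max(pcov[1, 1], 0.0))
    resid = y - model(t, *popt)
    in_range = tau_range[0] < tau < tau_range[1]
    if not in_range:
        warnings.warn(f"fitted tau_syn = {tau:.3g} ms outside plausible range {tau_range}")
    return KernelFit(
        tau_syn=float(tau), amplitude=float(a), offset=float(b),
        tau_ci=(float(tau - 1.96 * se), float(tau + 1.96 * se)),
        residual_norm=float(np.linalg.norm(resid)),
        in_range=in_range,
    )


def deconvolve(
    I: CurrentTrace,
    kernel: ReceptorKernel,
    lookahead: float | None = None,
) -> ScaledReleaseTrace:
    """Sequential constrained deconvolution of a leak-corrected current.

    Walks the trace one bin at a time.  With ``C(i)`` the current carried over
    from release asserted in earlier bins, the unconstrained release for bin
    ``i`` is ``p = (|I(i)| - C(i)) / (A*dt)``; it is clamped to ``p >= 0`` and
    capped so that the predicted current ``J(i) = C(i) + A*p*dt``, decaying
    with ``tau_syn``, never exceeds the measured magnitude anywhere within the
    lookahead window.  Release can therefore only be asserted if its future
    decay stays under the trace.

    The result is shifted by the kernel delay ``D`` so that ``q[i]`` is the
    scaled release rate at release time (pA/ms); the final ``D/dt`` bins,
    whose current lies beyond the trace, are zero.

    ``lookahead`` (ms) defaults to ``5 * tau_syn``; values below ``3*tau_syn``
    are rejected as too short for the constraint to be meaningful.
    """
    if lookahead is None:
        lookahead = 5.0 * kernel.tau_syn
    if lookahead < 3.0 * kernel.tau_syn:
        raise ValueError("lookahead must be at least 3*tau_syn")
    dt, tau, A = I.dt, kernel.tau_syn, abs(kernel.A)
    y = np.abs(np.asarray(I.I, dtype=float))
    n = len(y)
    # Forward-window minimum of |I(k)| * exp((k-i)*dt/tau) computed in log
    # space to avoid overflow for long traces.
    W = int(math.ceil(lookahead / dt))
    W += W % 2  # even width so the forward-aligned origin is admissible
    s = np.log(np.maximum(y, 1e-300)) + np.arange(n) * (dt / tau)
    m = minimum_filter1d(s, size=W + 1, mode="nearest", origin=-(W // 2))
    J_max = np.exp(m - np.arange(n) * (dt / tau))

    decay_f = math.exp(-dt / tau)
    q = np.zeros(n)
    C = 0.0
    Adt = A * dt
    for i in range(n):
        p_u = (y[i] - C) / Adt
        cap = (J_max[i] - C) / Adt
        p = min(max(p_u, 0.0), max(cap, 0.0))
        J = C + Adt * p
        q[i] = A * p
        C = J * decay_f
    nd = int(round(kernel.D / dt))
    if nd > 0:
        q = np.concatenate([q[nd:], np.zeros(nd)])
    return ScaledReleaseTrace(dt=dt, t0=I.t0, q=q)


def estimate_delay(
    spikes: np.ndarray,
    qtilde: ScaledReleaseTrace,
    window: float = 3.0,
) -> tuple[float, np.ndarray]:
    """Median lag between each spike and the following release-rate peak.

    For each spike the lag is the argmax of ``q~`` within ``(0, window]`` ms
    after it.  Spikes without a detectable peak (all-zero window, or the
    maximum sitting on the window's trailing edge) are excluded with a
    warning.  Returns ``(median_lag, per_spike_lags)``.
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size < 2:
        raise ValueError("need at least 2 spikes to estimate the delay")
    t = qtilde.times
    lags = []
    for tm in spikes:
        mask = (t > tm) & (t <= tm + window)
        idx = np.flatnonzero(mask)
        if idx.size == 0 or not np.any(qtilde.q[idx] > 0):
            warnings.warn(f"no detectable release peak after spike at {tm:g} ms")
            continue
        k = idx[np.argmax(qtilde.q[idx])]
        if k == idx[-1]:
            warnings.warn(f"release peak after spike at {tm:g} ms sits on the window edge")
            continue
        lags.append(t[k] - tm)
    if not lags:
        raise ValueError("no spike had a detectable release peak")
    lags = np.asarray(lags)
    return float(np.median(lags)), lags
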