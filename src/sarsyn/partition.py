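"""Spike-keyed synchronous/asynchronous release periods and their statistics.

A release-rate trace is partitioned into alternating windows keyed to the
spike train: a *synchronous* period after each spike (where release rises
sharply and falls within about a millisecond) and the *asynchronous* period
filling the gap until the next synchronous window (the last one runs to the
end of the trace).  Integrated release amounts per period and per trial,
``M_r(k, i)``, and their across-trial mean/SD are the sufficient statistics
the grid-search fit consumes.

Two window conventions are supported through ``sync_offset``:

* data convention (default, offset 0.3 ms): on deconvolved recordings the
  release rate rises ~0.3 ms after the spike artefact and the synchronous
  window is [t_k + 0.3, t_k + 1.4) ms;
* model convention (offset 0): on simulated release the synchronous event
  sits exactly in the spike bin, so the window starts at the spike itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Periods", "PeriodSummary", "define_periods", "integrate_release",
           "summarize_trials", "bin_period_index"]

SYNC_OFFSET = 0.3
SYNC_DURATION = 1.1


@dataclass(frozen=True)
class Periods:
    """Half-open period intervals per spike: sync[k] and async_[k], shape (K, 2)."""

    sync: np.ndarray
    async_: np.ndarray
    spikes: np.ndarray

    @property
    def n_spikes(self) -> int:
        return len(self.spikes)


def define_periods(
    spikes: np.ndarray,
    T: float,
    sync_offset: float = SYNC_OFFSET,
    sync_duration: float = SYNC_DURATION,
) -> Periods:
    """Build the synchronous/asynchronous period partition for a spike train.

    Sync period k is ``[t_k + offset, t_k + offset + duration)``, truncated at
    the next sync window's start if the spikes are closer than that.  Async
    period k fills the gap to the next sync window; the last one runs to T.
    Together the periods tile ``[t_1 + offset, T)`` without overlap.
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size == 0:
        raise ValueError("need at least one spike to define periods")
    if np.any(np.diff(spikes) <= sync_offset):
        raise ValueError("inter-spike interval must exceed sync_offset")
    starts = spikes + sync_offset
    ends = np.minimum(starts + sync_duration, np.append(starts[1:], T))
    sync = np.column_stack([starts, ends])
    a_starts = ends
    a_ends = np.append(starts[1:], T)
    async_ = np.column_stack([a_starts, np.maximum(a_ends, a_starts)])
    return Periods(sync=sync, async_=async_, spikes=spikes)


def bin_period_index(periods: Periods, n_bins: int, dt: float, t0: float = 0.0) -> np.ndarray:
    """Map each grid bin to a flat period index by bin-start membership.

    Flat layout: sync k -> k, async k -> K + k; bins outside all periods get
    -1.  Half-open intervals guarantee each bin lands in at most one period.
    """
    K = periods.n_spikes
    t = t0 + dt * np.arange(n_bins)
    pid = np.full(n_bins, -1, dtype=np.int64)
    for k in range(K):
        s, e = periods.sync[k]
        pid[(t >= s) & (t < e)] = k
        s, e = periods.async_[k]
        pid[(t >= s) & (t < e)] = K + k
    return pid


def integrate_release(
    q: np.ndarray,
    dt: float,
    periods: Periods,
    t0: float = 0.0,
    is_rate: bool = False,
) -> np.ndarray:
    """Integrated release per period for one trial.

    ``q`` holds per-bin amounts (default) or a rate (``is_rate=True``, in
    which case bins are weighted by dt).  Returns shape ``(2, K)``: row 0 the
    synchronous periods M_sr(k), row 1 the asynchronous M_ar(k).
    """
    q = np.asarray(q, dtype=float)
    pid = bin_period_index(periods, len(q), dt, t0)
    w = q * dt if is_rate else q
    K = periods.n_spikes
    M = np.zeros(2 * K)
    valid = pid >= 0
    np.add.at(M, pid[valid], w[valid])
    return np.vstack([M[:K], M[K:]])


@dataclass
class PeriodSummary:
    """Across-trial statistics of the integrated release amounts.

    ``mu``/``sigma`` have shape (2, K): row 0 synchronous, row 1 asynchronous.
    ``sigma`` is the *population* SD (divide by n, not n-1) — deliberate, and
    consequential at trial counts as small as 3 — floored at
    ``sigma_floor_frac`` times the grand-mean M so the Gaussian period
    likelihood stays finite.  ``n`` is the per-period trial count, ``M`` the
    raw per-trial amounts (n_trials, 2, K) with NaN where a trial lacks the
    period.
    """

    mu: np.ndarray
    sigma: np.ndarray
    n: np.ndarray
    M: np.ndarray
    sigma_raw: np.ndarray

    @property
    def n_spikes(self) -> int:
        return self.mu.shape[1]


def summarize_trials(
    trial_amounts: list[np.ndarray],
    sigma_floor_frac: float = 0.01,
) -> PeriodSummary:
    """Pool per-trial (2, K_i) period amounts into mean/SD per period.

    Trials may span different spike counts; shorter trials contribute NaN to
    the later periods and the per-period trial count ``n`` records how many
    trials cover each period.
    """
    if not trial_amounts:
        raise ValueError("need at least one trial")
    K = max(m.shape[1] for m in trial_amounts)
    stack = np.full((len(trial_amounts), 2, K), np.nan)
    for i, m in enumerate(trial_amounts):
        stack[i, :, : m.shape[1]] = m
    n = np.sum(~np.isnan(stack), axis=0)
    if np.any(n < 1):
        raise ValueError("every period needs at least one trial")
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(stack, axis=0)
        sigma_raw = np.sqrt(np.nanmean((stack - mu) ** 2, axis=0))  # population SD
    floor = sigma_floor_frac * float(np.nanmean(stack))
    sigma = np.maximum(sigma_raw, floor)
    return PeriodSummary(mu=mu, sigma=sigma, n=n, M=stack, sigma_raw=sigma_raw)
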