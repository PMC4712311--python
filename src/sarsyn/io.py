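"""Readers and writers for the package's tabular/JSON artifacts.

Dialects: CSV with a header row, decimal point, UTF-8.  Current traces carry
``time_ms,current_pA`` columns; release traces a tidy per-bin table; spike
trains are newline-separated floats (ms) or a JSON list; parameters and
kernels are flat JSON objects.  All writers round-trip losslessly through the
corresponding reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .partition import PeriodSummary
from .receptor import CurrentTrace, ReceptorKernel
from .sar_core import ReleaseTrace, SARParams

__all__ = [
    "read_trace", "write_trace", "read_spikes", "write_spikes",
    "read_params", "write_params", "read_kernel", "write_kernel",
    "write_release_trace", "write_period_amounts", "read_qtilde", "write_qtilde",
    "write_summary", "read_summary", "write_result",
]

#: maximal tolerated sampling jitter, relative to dt.
_JITTER = 1e-6


class FormatError(ValueError):
    """Structured file-format error carrying the offending line where known."""


def _check_uniform_time(t: np.ndarray, path) -> float:
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if dt <= 0:
        bad = int(np.argmax(dts <= 0))
        raise FormatError(f"{path}: non-monotonic time at data line {bad + 2}")
    jitter = np.abs(dts - dt)
    if np.any(jitter > _JITTER * dt):
        bad = int(np.argmax(jitter > _JITTER * dt))
        raise FormatError(f"{path}: non-uniform sampling at data line {bad + 2}")
    return dt


def read_trace(path) -> CurrentTrace:
    """Read a current trace CSV (columns time_ms, current_pA; negative IPSC)."""
    df = pd.read_csv(path)
    for col in ("time_ms", "current_pA"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["current_pA"].isna().any():
        bad = int(df["current_pA"].isna().idxmax())
        raise FormatError(f"{path}: NaN current at data line {bad + 2}")
    t = df["time_ms"].to_numpy(dtype=float)
    dt = _check_uniform_time(t, path)
    return CurrentTrace(dt=dt, t0=float(t[0]), I=df["current_pA"].to_numpy(dtype=float))


def write_trace(trace: CurrentTrace, path) -> None:
    pd.DataFrame({"time_ms": trace.times, "current_pA": trace.I}).to_csv(path, index=False)


def read_spikes(path) -> np.ndarray:
    """Spike times in ms: newline-separated floats, or a JSON list for .json."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            times = np.asarray(json.load(fh), dtype=float)
    else:
        times = np.loadtxt(path, ndmin=1, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise FormatError(f"{path}: spike times must be strictly increasing")
    if times.size and times[0] < 0:
        raise FormatError(f"{path}: negative spike time")
    return times


def write_spikes(times: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(list(map(float, times)), fh)
    else:
        np.savetxt(path, np.asarray(times, dtype=float), fmt="%.10g")


def read_params(path) -> SARParams:
    """Parameter JSON; missing U0/D fall back to the defaults (0 and 0.75 ms)."""
    return SARParams.from_json(path)


def write_params(params: SARParams, path) -> None:
    params.to_json(path)


def read_kernel(path) -> ReceptorKernel:
    return ReceptorKernel.from_json(path)


def write_kernel(kernel: ReceptorKernel, path) -> None:
    kernel.to_json(path)


def write_release_trace(trace: ReleaseTrace, path) -> None:
    """Tidy per-bin CSV of a simulated trial."""
    cols = {"time_ms": trace.times, "q_sr": trace.q_sr, "q_ar": trace.q_ar}
    if trace.mode == "stochastic":
        cols.update({"n_sr": trace.n_sr, "n_ar": trace.n_ar, "r": trace.r})
    cols.update({"u_sr": trace.u_sr, "u_ar": trace.u_ar})
    if trace.mode == "stochastic":
        cols["N"] = trace.N
    else:
        cols["x"] = trace.x
    pd.DataFrame(cols).to_csv(path, index=False)


def write_period_amounts(trial_amounts: list[np.ndarray], path) -> None:
    """Per-trial period CSV: kind, spike_k, trial_i, M."""
    rows = []
    for i, m in enumerate(trial_amounts):
        for r_i, kind in enumerate(("sr", "ar")):
            for k in range(m.shape[1]):
                rows.append({"kind": kind, "spike_k": k + 1,
                             "trial_i": i + 1, "M": m[r_i, k]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_qtilde(times: np.ndarray, q: np.ndarray, path) -> None:
    pd.DataFrame({"time_ms": times, "q_scaled_pA": q}).to_csv(path, index=False)


def read_qtilde(path) -> tuple[np.ndarray, np.ndarray, float]:
    df = pd.read_csv(path)
    for col in ("time_ms", "q_scaled_pA"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    t = df["time_ms"].to_numpy(dtype=float)
    dt = _check_uniform_time(t, path)
    return t, df["q_scaled_pA"].to_numpy(dtype=float), dt


def write_summary(summary: PeriodSummary, path) -> None:
    """Summary CSV: kind, spike_k, mu, sigma, n (sigma is the floored SD)."""
    K = summary.n_spikes
    rows = []
    for r_i, kind in enumerate(("sr", "ar")):
        for k in range(K):
            rows.append({
                "kind": kind, "spike_k": k + 1,
                "mu": summary.mu[r_i, k], "sigma": summary.sigma[r_i, k],
                "n": int(summary.n[r_i, k]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_summary(path) -> PeriodSummary:
    df = pd.read_csv(path)
    K = int(df["spike_k"].max())
    mu = np.zeros((2, K))
    sigma = np.zeros((2, K))
    n = np.zeros((2, K), dtype=int)
    for r_i, kind in enumerate(("sr", "ar")):
        sub = df[df["kind"] == kind].sort_values("spike_k")
        if len(sub) != K:
            raise FormatError(f"{path}: expected {K} rows of kind {kind!r}")
        mu[r_i] = sub["mu"].to_numpy()
        sigma[r_i] = sub["sigma"].to_numpy()
        n[r_i] = sub["n"].to_numpy()
    return PeriodSummary(mu=mu, sigma=sigma, n=n, M=np.empty((0, 2, K)), sigma_raw=sigma)


def write_result(payload: dict, path) -> None:
    """JSON result writer; numpy types are converted to plain Python."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"cannot serialise {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
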