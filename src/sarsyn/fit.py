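"""Grid-search maximum-likelihood inference of SAR parameters.

The fit consumes per-period release statistics (mean mu_r(k) and population SD
sigma_r(k) over trials) and compares them against the *deterministic*
mean-field prediction of the model, period by period, under an independent
Gaussian likelihood:

    log P(M | theta) = sum_r sum_k [ -(Mtilde_r(k) - mu_r(k))^2 / (2 sigma_r(k)^2)
                                     - log(sqrt(2 pi) sigma_r(k)) ]

Because the postsynaptic gain A and the full resource X_F only scale the
release amounts, predictions are computed with X_F = 1 and rescaled so that
their total matches the data total (the A-normalisation); X_F is therefore not
a fitted quantity.  Likewise U_max and U_ar are close to redundant — both
scale the spike-triggered jump of the asynchronous release rate — so the
asynchronous increment can be gridded either directly (``U_ar``, bounded by
its physiological range, as in the validation study) or through the product
``c_ar = U_max * U_ar`` (which matches the redundancy structure); results
always report both, with the missing one backed out via U_max.

The search itself is an exhaustive evaluation over the Cartesian parameter
grid (vectorised across grid points), optionally in the two-stage scheme:
coarse search over all six parameters, then a finer search over
{tau_sr, tau_ar, c_ar, U_max} with U_sr and tau_d fixed at their first-stage
estimates.  Ties are broken by the first grid point in lexicographic order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from . import partition as _partition
from .partition import PeriodSummary, Periods, bin_period_index, define_periods
from .sar_core import DEFAULT_DT, snap_spikes

__all__ = [
    "PARAM_ORDER",
    "SpikeProtocol",
    "FitConfig",
    "FitResult",
    "predict_periods",
    "log_likelihood",
    "grid_search",
    "two_stage_fit",
    "confidence_intervals",
    "quantum_size",
    "QuantumSizeResult",
]

#: canonical free-parameter order used for grids and tie-breaking.  The
#: asynchronous increment may be parametrised either directly (``U_ar``) or
#: through the product ``c_ar = U_max * U_ar``; exactly one of the two is
#: gridded/fixed in any configuration.
PARAM_ORDER = ("tau_sr", "U_sr", "tau_ar", "U_ar", "c_ar", "tau_d", "U_max")
BASE_PARAMS = ("tau_sr", "U_sr", "tau_ar", "tau_d", "U_max")


@dataclass(frozen=True)
class SpikeProtocol:
    """Stimulation protocol: regular spike train and simulation grid."""

    n_spikes: int = 10
    rate_hz: float = 100.0
    dt: float = DEFAULT_DT
    t_first: float = 0.0
    T: float | None = None  # default: one inter-spike interval past the last spike
    sync_offset: float = 0.0  # model convention: sync period starts at the spike
    sync_duration: float = _partition.SYNC_DURATION

    @property
    def isi(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def spikes(self) -> np.ndarray:
        return self.t_first + self.isi * np.arange(self.n_spikes)

    @property
    def duration(self) -> float:
        return self.T if self.T is not None else float(self.spikes[-1] + self.isi)

    def periods(self) -> Periods:
        return define_periods(
            self.spikes, self.duration,
            sync_offset=self.sync_offset, sync_duration=self.sync_duration,
        )


@dataclass
class FitConfig:
    """Grid-search configuration.

    ``grids`` maps free-parameter names (from :data:`PARAM_ORDER`) to value
    arrays; ``fixed`` holds parameters excluded from the search.  ``n_sp`` is
    the number of spike periods entering the likelihood.
    """

    grids: dict[str, np.ndarray]
    protocol: SpikeProtocol
    fixed: dict[str, float] = field(default_factory=dict)
    n_sp: int = 10
    U0: float = 0.0

    def __post_init__(self) -> None:
        overlap = set(self.grids) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both fixed and gridded: {sorted(overlap)}")
        unknown = (set(self.grids) | set(self.fixed)) - set(PARAM_ORDER)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        present = set(self.grids) | set(self.fixed)
        missing = set(BASE_PARAMS) - present
        if missing:
            raise ValueError(f"parameters neither fixed nor gridded: {sorted(missing)}")
        n_async = len(present & {"U_ar", "c_ar"})
        if n_async != 1:
            raise ValueError("exactly one of U_ar or c_ar must be gridded or fixed")
        for name, g in self.grids.items():
            g = np.asarray(g, dtype=float)
            if g.size == 0:
                raise ValueError(f"empty grid for {name}")
            self.grids[name] = g


@dataclass
class FitResult:
    """Outcome of a grid search."""

    theta: dict[str, float]  # includes U_ar backed out of c_ar
    log_l: float
    M_pred: np.ndarray  # (2, K) scaled predictions at theta-hat
    scale: float  # A-normalisation factor applied to the raw predictions
    config: FitConfig
    grid_log_l: np.ndarray | None = None
    intervals: dict[str, tuple[float, float]] | None = None


def _sim_grid_periods(
    theta: dict[str, np.ndarray],
    protocol: SpikeProtocol,
    U0: float = 0.0,
) -> np.ndarray:
    """Deterministic per-period release amounts, vectorised over grid points.

    All six entries of ``theta`` are broadcastable arrays of a common shape
    (G,).  Runs the mean-field model with X_F = 1 on the protocol's grid and
    accumulates release into the period partition.  Returns (G, 2, K) raw
    (unnormalised) amounts.
    """
    dt = protocol.dt
    n_bins = int(math.ceil(protocol.duration / dt))
    spike_bins = snap_spikes(protocol.spikes, dt, n_bins)
    periods = protocol.periods()
    pid = bin_period_index(periods, n_bins, dt)
    K = periods.n_spikes

    tau_sr = np.atleast_1d(np.asarray(theta["tau_sr"], dtype=float))
    U_sr = np.atleast_1d(np.asarray(theta["U_sr"], dtype=float))
    tau_ar = np.atleast_1d(np.asarray(theta["tau_ar"], dtype=float))
    tau_d = np.atleast_1d(np.asarray(theta["tau_d"], dtype=float))
    U_max = np.atleast_1d(np.asarray(theta["U_max"], dtype=float))
    if "U_ar" in theta:
        U_ar = np.atleast_1d(np.asarray(theta["U_ar"], dtype=float))
    else:
        U_ar = np.atleast_1d(np.asarray(theta["c_ar"], dtype=float)) / U_max
    (tau_sr, U_sr, tau_ar, U_ar, tau_d, U_max) = np.broadcast_arrays(
        tau_sr, U_sr, tau_ar, U_ar, tau_d, U_max
    )
    G = tau_sr.shape[0]

    f_sr = np.exp(-dt / tau_sr)
    f_ar = np.exp(-dt / tau_ar)
    inv_td = 1.0 / tau_d

    u_sr = np.zeros(G)
    u_ar = np.full(G, U0)
    x = np.ones(G)  # X_F = 1
    M = np.zeros((G, 2 * K))
    is_spike = np.zeros(n_bins, dtype=bool)
    is_spike[spike_bins] = True

    for i in range(n_bins):
        p = pid[i]
        if is_spike[i]:
            u_sr = u_sr + U_sr * (1.0 - u_sr)
            u_ar = u_ar + U_ar * (U_max - u_ar)
            q_sr = u_sr * x
            x = x - q_sr
            if p >= 0:
                M[:, p] += q_sr
        q_ar = x * u_ar * dt
        if p >= 0:
            M[:, p] += q_ar
        a = inv_td + u_ar
        x_inf = inv_td / a
        x = x_inf + (x - x_inf) * np.exp(-a * dt)
        u_sr = u_sr * f_sr
        u_ar = U0 + (u_ar - U0) * f_ar
    return M.reshape(G, 2, K)


def predict_periods(
    theta: dict[str, float],
    protocol: SpikeProtocol,
    summary: PeriodSummary,
    n_sp: int | None = None,
    U0: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Model-predicted period amounts, A-normalised to the data total.

    ``theta`` uses either ``U_ar`` or the product ``c_ar`` (with ``U_max``).
    The raw deterministic prediction (computed at X_F = 1; any other X_F gives
    the same result after normalisation) is scaled by a single factor so that
    the sum of the first ``n_sp`` periods of both kinds matches the
    corresponding sum of the data means.  Returns ``(M_pred (2, K), scale)``.
    """
    theta = dict(theta)
    n_sp = n_sp if n_sp is not None else summary.n_spikes
    raw = _sim_grid_periods(theta, protocol, U0=U0)[0]
    data_total = float(np.nansum(summary.mu[:, :n_sp]))
    pred_total = float(raw[:, :n_sp].sum())
    scale = data_total / pred_total if pred_total > 0 else 0.0
    return raw * scale, scale


def log_likelihood(M_pred: np.ndarray, summary: PeriodSummary, n_sp: int | None = None) -> np.ndarray | float:
    """Gaussian period log-likelihood of predictions against the summary.

    ``M_pred`` has shape (2, K) or (G, 2, K); summation runs over both release
    kinds and the first ``n_sp`` spike periods.  Uses the summary's (floored,
    population) sigma.
    """
    n_sp = n_sp if n_sp is not None else summary.n_spikes
    mu = summary.mu[:, :n_sp]
    sigma = summary.sigma[:, :n_sp]
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))):
        raise ValueError("summary contains non-finite mu/sigma in the fitted range")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive (apply the summary floor)")
    pred = np.asarray(M_pred, dtype=float)[..., :, :n_sp]
    if not np.all(np.isfinite(pred)):
        raise ValueError("non-finite predictions")
    z2 = (pred - mu) ** 2 / (2.0 * sigma**2)
    terms = -z2 - np.log(np.sqrt(2.0 * np.pi) * sigma)
    out = terms.sum(axis=(-2, -1))
    return float(out) if out.ndim == 0 else out


def _grid_mesh(config: FitConfig) -> tuple[list[str], dict[str, np.ndarray]]:
    free = [p for p in PARAM_ORDER if p in config.grids]
    axes = [config.grids[p] for p in free]
    mesh = np.meshgrid(*axes, indexing="ij")
    theta = {p: m.ravel() for p, m in zip(free, mesh)}
    for p, v in config.fixed.items():
        theta[p] = np.full(theta[free[0]].shape if free else 1, float(v))
    return free, theta


def grid_search(summary: PeriodSummary, config: FitConfig) -> FitResult:
    """Exhaustive maximum-likelihood search over the Cartesian grid.

    Every grid point is simulated (vectorised), A-normalised against the data
    and scored with :func:`log_likelihood`; the argmax wins, ties going to the
    first point in lexicographic order of :data:`PARAM_ORDER`.
    """
    free, theta = _grid_mesh(config)
    raw = _sim_grid_periods(theta, config.protocol, U0=config.U0)
    n_sp = config.n_sp
    data_total = float(np.nansum(summary.mu[:, :n_sp]))
    pred_tot = raw[:, :, :n_sp].sum(axis=(1, 2))
    scale = np.where(pred_tot > 0, data_total / np.where(pred_tot > 0, pred_tot, 1.0), 0.0)
    M_pred = raw * scale[:, None, None]
    ll = log_likelihood(M_pred, summary, n_sp=n_sp)
    best = int(np.argmax(ll))
    theta_hat = {p: float(theta[p][best]) for p in theta}
    if "U_ar" in theta_hat:
        theta_hat["c_ar"] = theta_hat["U_ar"] * theta_hat["U_max"]
    else:
        theta_hat["U_ar"] = theta_hat["c_ar"] / theta_hat["U_max"]
    return FitResult(
        theta=theta_hat, log_l=float(ll[best]), M_pred=M_pred[best],
        scale=float(scale[best]), config=config, grid_log_l=ll,
    )


#: stage-2 grid density per free parameter.  tau_ar and the product c_ar sit
#: on a likelihood ridge (a relative error in one trades against the other),
#: so both need fine resolution — c_ar on a log grid, since it acts as a
#: scale parameter spanning more than a decade.
STAGE2_POINTS: dict[str, int] = {"tau_sr": 13, "tau_ar": 25, "U_ar": 21,
                                 "c_ar": 21, "U_max": 9}

#: parameters whose grids are geometrically spaced.
LOG_PARAMS = ("U_ar", "c_ar")


def _spaced(lo: float, hi: float, points: int, name: str) -> np.ndarray:
    if name in LOG_PARAMS and lo > 0:
        return np.geomspace(lo, hi, points)
    return np.linspace(lo, hi, points)


def two_stage_fit(
    summary: PeriodSummary,
    config: FitConfig,
    stage2_points: int | dict[str, int] | None = None,
    stage2_free: tuple[str, ...] = ("tau_sr", "tau_ar", "U_ar", "c_ar", "U_max"),
) -> tuple[FitResult, FitResult]:
    """Coarse all-parameter search, then a finer search over the remaining
    free parameters with the well-identified pair {U_sr, tau_d} fixed at its
    first-stage estimate.

    Stage-2 grids span the same ranges as stage 1 with per-parameter point
    counts from ``stage2_points`` (default :data:`STAGE2_POINTS`).  Returns
    ``(stage1, stage2)`` results; the stage-2 theta is the final estimate.
    """
    stage1 = grid_search(summary, config)
    stage2_free = tuple(p for p in stage2_free if p in config.grids)
    if not stage2_free:
        raise ValueError("no stage-2 free parameter was gridded in stage 1")
    if stage2_points is None:
        points = dict(STAGE2_POINTS)
    elif isinstance(stage2_points, int):
        points = {p: stage2_points for p in stage2_free}
    else:
        points = {**STAGE2_POINTS, **stage2_points}
    grids2 = {
        p: _spaced(float(np.min(config.grids[p])), float(np.max(config.grids[p])),
                   points.get(p, 9), p)
        for p in stage2_free
    }
    # stage1.theta carries estimates for gridded and values for fixed parameters
    stage1_names = set(config.grids) | set(config.fixed)
    fixed2 = {p: stage1.theta[p] for p in stage1_names if p not in stage2_free}
    config2 = FitConfig(
        grids=grids2, protocol=config.protocol, fixed=fixed2,
        n_sp=config.n_sp, U0=config.U0,
    )
    stage2 = grid_search(summary, config2)
    return stage1, stage2


def confidence_intervals(
    summary: PeriodSummary,
    result: FitResult,
    refine_factor: int = 10,
    level: float = 0.9,
) -> dict[str, tuple[float, float, bool, bool]]:
    """Per-parameter likelihood-ratio intervals around the estimate.

    For each free parameter a finer grid (``refine_factor`` times the original
    point count) spanning the original search range is scanned while all other
    parameters stay at theta-hat.  The interval is the set of scanned values
    whose *likelihood* (not log) stays above ``level`` of the scan maximum,
    i.e. log L >= log L_max + ln(level).  Returns per parameter
    ``(lo, hi, open_lo, open_hi)`` where the flags mark intervals that touch
    the scanned range's boundary (open-ended as far as the scan can tell).
    """
    config = result.config
    out: dict[str, tuple[float, float, bool, bool]] = {}
    for p, g in config.grids.items():
        scan = np.linspace(float(np.min(g)), float(np.max(g)), refine_factor * len(g))
        names = set(config.grids) | set(config.fixed)
        theta = {q: np.full(scan.shape, result.theta[q]) for q in names}
        theta[p] = scan
        raw = _sim_grid_periods(theta, config.protocol, U0=config.U0)
        n_sp = config.n_sp
        data_total = float(np.nansum(summary.mu[:, :n_sp]))
        pred_tot = raw[:, :, :n_sp].sum(axis=(1, 2))
        sc = np.where(pred_tot > 0, data_total / np.where(pred_tot > 0, pred_tot, 1.0), 0.0)
        ll = log_likelihood(raw * sc[:, None, None], summary, n_sp=n_sp)
        keep = ll >= ll.max() + math.log(level)
        vals = scan[keep]
        out[p] = (float(vals.min()), float(vals.max()),
                  bool(keep[0]), bool(keep[-1]))
    return out


@dataclass
class QuantumSizeResult:
    """Fano-factor regression estimate of the quantal current amplitude."""

    x0_tilde: float  # pA, slope of across-trial variance vs mean of binned release
    r_squared: float
    mean: np.ndarray  # per-bin across-trial mean of M(j) (pA)
    var: np.ndarray  # per-bin across-trial variance (pA^2)
    intercept: float  # 0.0 for the through-origin fit
    n_bins: int
    n_trials: int


def quantum_size(
    segments: np.ndarray | list[np.ndarray],
    dt: float,
    bin_ms: float = 3.9,
    through_origin: bool = True,
) -> QuantumSizeResult:
    """Estimate the quantal amplitude from post-train asynchronous release.

    ``segments`` stacks the scaled release rate q~ (pA/ms) of one tail segment
    per trial (equal lengths, same grid).  Time is cut into bins of
    ``bin_ms``; per trial and bin, M(j) = sum(q~ dt).  If single quanta of
    amplitude x0~ arrive as a (locally homogeneous) Poisson process, the Fano
    factor of M(j) across trials equals x0~ in every bin, so the slope of the
    across-trial variance against the mean — by default a regression through
    the origin — estimates x0~ (pA).
    """
    seg = np.asarray(segments, dtype=float)
    if seg.ndim != 2:
        raise ValueError("segments must stack to a (n_trials, n_samples) array")
    n_trials, n_samples = seg.shape
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    per_bin = int(round(bin_ms / dt))
    n_bins = n_samples // per_bin
    if n_bins < 3:
        raise ValueError("fewer than 3 usable bins; supply a longer tail segment")
    M = seg[:, : n_bins * per_bin].reshape(n_trials, n_bins, per_bin).sum(axis=2) * dt
    mean = M.mean(axis=0)
    var = M.var(axis=0, ddof=1)
    if through_origin:
        slope = float(np.dot(mean, var) / np.dot(mean, mean))
        resid = var - slope * mean
        ss_tot = float(np.sum((var - var.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        intercept = 0.0
    else:
        res = linregress(mean, var)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    return QuantumSizeResult(
        x0_tilde=slope, r_squared=r2, mean=mean, var=var,
        intercept=intercept, n_bins=n_bins, n_trials=n_trials,
    )
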