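"""Synthetic voltage-clamp fixtures and the parameter-recovery study.

``make_fixture`` emulates what an IPSC recording rig produces: stochastic SAR
release convolved with a delayed exponential receptor kernel, flipped to the
negative-going inhibitory sign, offset by a constant leak current and overlaid
with i.i.d. Gaussian noise.  The ground-truth release is kept alongside, so
round-trip tests of the inverse pipeline can compare against it.

``recovery_experiment`` is the simulation study validating the grid-search
fit: parameter settings are drawn uniformly from stated ranges, stochastic
release is simulated for a regular spike train over many trials, each setting
is fitted by the two-stage grid search on period summaries of the *release*
itself (not of deconvolved currents — deconvolution accuracy is a separate
concern, tested by its own round trip), and the estimates are regressed
against the truths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from .fit import (
    FitConfig,
    SpikeProtocol,
    log_likelihood,
    predict_periods,
    two_stage_fit,
)
from .partition import integrate_release, summarize_trials
from .receptor import CurrentTrace, ReceptorKernel, release_to_current
from .sar_core import DEFAULT_DT, ReleaseEnsemble, SARParams, simulate_trials

__all__ = [
    "RECOVERY_RANGES",
    "make_fixture",
    "recovery_experiment",
    "RecoveryReport",
    "default_recovery_grids",
]

#: uniform sampling ranges of the recovery study's true parameters.
RECOVERY_RANGES: dict[str, tuple[float, float]] = {
    "tau_sr": (4.0, 10.0),
    "U_sr": (0.1, 0.5),
    "tau_ar": (8.0, 20.0),
    "U_ar": (0.004, 0.02),
    "tau_d": (20.0, 80.0),
    "U_max": (0.2, 1.0),
}

RECOVERY_N_F = 271


def make_fixture(
    params: SARParams,
    protocol: SpikeProtocol,
    kernel: ReceptorKernel,
    n_trials: int = 1,
    noise_sd: float = 2.0,
    leak: float = -15.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[CurrentTrace], ReleaseEnsemble]:
    """Simulate raw IPSC recordings with known ground truth.

    Per trial: stochastic SAR release -> receptor convolution (delay from the
    kernel) -> raw current ``leak - I_magnitude + noise`` (negative-going
    IPSC riding on a constant leak offset with Gaussian noise of ``noise_sd``
    pA).  Returns the raw traces and the underlying release ensemble.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ens = simulate_trials(
        params, protocol.spikes, protocol.duration, dt=protocol.dt,
        n_trials=n_trials, seed=rng,
    )
    traces = []
    for i in range(n_trials):
        mag = release_to_current(
            ens.q_sr[i] + ens.q_ar[i], kernel, dt=ens.dt, t0=ens.t0
        ).I
        noise = rng.normal(0.0, noise_sd, size=mag.shape) if noise_sd > 0 else 0.0
        traces.append(CurrentTrace(dt=ens.dt, t0=ens.t0, I=leak - mag + noise, kind="raw"))
    return traces, ens


def default_recovery_grids(
    ranges: dict[str, tuple[float, float]] = RECOVERY_RANGES,
    points: int = 5,
    strong_points: int = 9,
) -> dict[str, np.ndarray]:
    """Stage-1 grids spanning the truth ranges (product space for U_ar).

    Grid density is anisotropic: U_sr and tau_d dominate the likelihood (they
    set the depressing synchronous envelope) and get ``strong_points`` values
    — their stage-1 estimates are frozen afterwards, so quantising them
    coarsely would leak bias into every stage-2 parameter.  The weakly
    identified dimensions get ``points`` values and are refined in stage 2.
    U_ar is gridded directly within its physiological range (geometrically
    spaced — it acts multiplicatively on the asynchronous release); only the
    product U_max*U_ar is well identified, and constraining U_ar to its own
    bounded range is what couples the U_max estimate to the product.
    """
    return {
        "tau_sr": np.linspace(*ranges["tau_sr"], points),
        "U_sr": np.linspace(*ranges["U_sr"], strong_points),
        "tau_ar": np.linspace(*ranges["tau_ar"], points),
        "U_ar": np.geomspace(*ranges["U_ar"], points),
        "tau_d": np.linspace(*ranges["tau_d"], strong_points),
        "U_max": np.linspace(*ranges["U_max"], points),
    }


@dataclass
class RecoveryReport:
    """Result of the parameter-recovery experiment.

    ``r2`` holds the squared Pearson correlation of estimated vs true values
    per parameter (plus the product ``c_ar = U_max*U_ar``); ``rel_dev_pct`` is
    the mean relative deviation (in %) between the log-likelihood of the
    estimate and of the truth on the same simulated summaries.
    """

    theta_true: dict[str, np.ndarray]
    theta_hat: dict[str, np.ndarray]
    log_l_hat: np.ndarray
    log_l_true: np.ndarray
    r2: dict[str, float]
    rel_dev_pct: float
    n_settings: int
    n_trials: int
    seed: int | None
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "n_settings": self.n_settings,
            "n_trials": self.n_trials,
            "seed": self.seed,
            "r2": self.r2,
            "rel_dev_pct": self.rel_dev_pct,
            "log_l_hat": self.log_l_hat.tolist(),
            "log_l_true": self.log_l_true.tolist(),
            "theta_true": {k: v.tolist() for k, v in self.theta_true.items()},
            "theta_hat": {k: v.tolist() for k, v in self.theta_hat.items()},
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _r2(true: np.ndarray, est: np.ndarray) -> float:
    """Squared Pearson correlation of estimates against truths."""
    if np.ptp(est) == 0 or np.ptp(true) == 0:
        return 0.0
    return float(linregress(true, est).rvalue ** 2)


def recovery_experiment(
    n_settings: int = 30,
    trials: int = 50,
    ranges: dict[str, tuple[float, float]] | None = None,
    n_spikes: int = 25,
    rate_hz: float = 100.0,
    dt: float = DEFAULT_DT,
    stage1_points: int = 5,
    stage2_points: int | dict[str, int] | None = None,
    seed: int | None = 0,
    N_F: int = RECOVERY_N_F,
) -> RecoveryReport:
    """Validate the two-stage grid-search fit on simulated ground truth.

    For each of ``n_settings`` parameter settings drawn uniformly from
    ``ranges``: simulate ``trials`` stochastic trials of ``n_spikes`` spikes
    at ``rate_hz``, summarise total release per sync/async period, fit by the
    two-stage grid search (all periods enter the likelihood), and record the
    estimate and the log-likelihoods of estimate and truth.  R-squared values
    of estimated-vs-true are computed per parameter and for the product
    U_max*U_ar.
    """
    ranges = dict(RECOVERY_RANGES if ranges is None else ranges)
    if set(ranges) != set(RECOVERY_RANGES):
        raise ValueError(f"ranges must cover exactly {sorted(RECOVERY_RANGES)}")
    for p, (lo, hi) in ranges.items():
        if lo >= hi:
            raise ValueError(f"empty range for {p}")
    grids = default_recovery_grids(ranges, points=stage1_points)
    for p in ("tau_sr", "U_sr", "tau_ar", "U_ar", "tau_d", "U_max"):
        g = grids[p]
        if g.min() > ranges[p][0] or g.max() < ranges[p][1]:
            raise ValueError(f"grid for {p} does not cover the sampling range")

    protocol = SpikeProtocol(n_spikes=n_spikes, rate_hz=rate_hz, dt=dt, sync_offset=0.0)
    periods = protocol.periods()
    ss = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    trial_seeds = ss.spawn(n_settings)

    names = list(RECOVERY_RANGES)
    theta_true = {p: np.empty(n_settings) for p in names + ["c_ar"]}
    theta_hat = {p: np.empty(n_settings) for p in names + ["c_ar"]}
    ll_hat = np.empty(n_settings)
    ll_true = np.empty(n_settings)

    for s in range(n_settings):
        truth = {p: float(draw_rng.uniform(*ranges[p])) for p in names}
        truth_params = SARParams(
            tau_sr=truth["tau_sr"], U_sr=truth["U_sr"], tau_ar=truth["tau_ar"],
            U_ar=truth["U_ar"], U_max=truth["U_max"], tau_d=truth["tau_d"],
            N_F=N_F, x0=1.0,
        )
        ens = simulate_trials(
            truth_params, protocol.spikes, protocol.duration, dt=dt,
            n_trials=trials, seed=np.random.default_rng(trial_seeds[s]),
        )
        amounts = [
            integrate_release(ens.q_sr[i] + ens.q_ar[i], dt, periods)
            for i in range(trials)
        ]
        summary = summarize_trials(amounts)
        config = FitConfig(grids=dict(grids), protocol=protocol, n_sp=n_spikes)
        _, stage2 = two_stage_fit(summary, config, stage2_points=stage2_points)

        for p in names:
            theta_true[p][s] = truth[p]
            theta_hat[p][s] = stage2.theta[p]
        theta_true["c_ar"][s] = truth["U_ar"] * truth["U_max"]
        theta_hat["c_ar"][s] = stage2.theta["c_ar"]
        ll_hat[s] = stage2.log_l
        M_true, _ = predict_periods(truth, protocol, summary, n_sp=n_spikes)
        ll_true[s] = log_likelihood(M_true, summary, n_sp=n_spikes)

    r2 = {p: _r2(theta_true[p], theta_hat[p]) for p in names + ["c_ar"]}
    rel_dev = float(np.mean(np.abs(ll_hat - ll_true) / np.abs(ll_true))) * 100.0
    return RecoveryReport(
        theta_true=theta_true, theta_hat=theta_hat,
        log_l_hat=ll_hat, log_l_true=ll_true,
        r2=r2, rel_dev_pct=rel_dev,
        n_settings=n_settings, n_trials=trials, seed=seed,
        config={
            "n_spikes": n_spikes, "rate_hz": rate_hz, "dt": dt,
            "stage1_points": stage1_points, "stage2_points": stage2_points or "default",
            "ranges": {k: list(v) for k, v in ranges.items()}, "N_F": N_F,
        },
    )
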