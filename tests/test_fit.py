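"""Grid-search likelihood fitting and quantal-size estimation tests."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from sarsyn import (
    FitConfig,
    SARParams,
    SpikeProtocol,
    confidence_intervals,
    grid_search,
    integrate_release,
    log_likelihood,
    predict_periods,
    quantum_size,
    simulate_trials,
    summarize_trials,
)
from sarsyn.partition import PeriodSummary


def summary_from(mu, sigma):
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    return PeriodSummary(mu=mu, sigma=sigma, n=np.full(mu.shape, 10),
                         M=np.empty((0, *mu.shape)), sigma_raw=sigma)


PROTOCOL = SpikeProtocol(n_spikes=10, rate_hz=100.0, dt=0.05, sync_offset=0.0)

THETA = {"tau_sr": 2.0, "U_sr": 0.3, "tau_ar": 12.0, "U_ar": 0.01,
         "U_max": 0.5, "tau_d": 30.0}


class TestLogLikelihood:
    def test_zero_residual_leaves_only_normalisers(self):
        mu = np.full((2, 4), 3.0)
        sigma = np.full((2, 4), 0.7)
        s = summary_from(mu, sigma)
        expected = -8 * math.log(math.sqrt(2 * math.pi) * 0.7)
        assert log_likelihood(mu, s) == pytest.approx(expected)

    def test_single_period_hand_value(self):
        s = summary_from([[1.0]], [[1.0]])
        # residual 1, sigma 1: -1/2 - log sqrt(2 pi)
        assert log_likelihood(np.array([[2.0]]), s) == pytest.approx(
            -0.5 - math.log(math.sqrt(2 * math.pi))
        )

    def test_agrees_with_scipy_normal_logpdf(self, rng):
        mu = rng.uniform(1, 5, (2, 6))
        sigma = rng.uniform(0.2, 2, (2, 6))
        pred = mu + rng.normal(0, 1, (2, 6))
        s = summary_from(mu, sigma)
        oracle = norm.logpdf(pred, loc=mu, scale=sigma).sum()
        assert log_likelihood(pred, s) == pytest.approx(oracle, rel=1e-12)

    def test_invariant_to_trial_relabelling(self, rng):
        trials = [rng.uniform(0, 5, (2, 6)) for _ in range(8)]
        s1 = summarize_trials(trials)
        s2 = summarize_trials(trials[::-1])
        pred = rng.uniform(0, 5, (2, 6))
        assert log_likelihood(pred, s1) == pytest.approx(log_likelihood(pred, s2))


class TestPredictPeriods:
    def test_normalisation_contract(self):
        s = summary_from(np.arange(20, dtype=float).reshape(2, 10) + 1,
                         np.ones((2, 10)))
        M, _ = predict_periods(THETA, PROTOCOL, s)
        assert M.sum() == pytest.approx(s.mu.sum())

    def test_async_predictions_vanish_when_u_ar_zero(self):
        s = summary_from(np.ones((2, 10)), np.ones((2, 10)))
        theta = dict(THETA, U_ar=0.0)
        M, _ = predict_periods(theta, PROTOCOL, s)
        np.testing.assert_allclose(M[1], 0.0, atol=1e-15)

    def test_invariant_to_resource_scale(self):
        """After A-normalisation the prediction cannot depend on X_F: the
        same theta applied to data generated at any overall scale gives
        identical normalised periods."""
        s = summary_from(np.arange(20, dtype=float).reshape(2, 10) + 1,
                         np.ones((2, 10)))
        M1, _ = predict_periods(THETA, PROTOCOL, s)
        s10 = summary_from(s.mu * 10, s.sigma)
        M10, _ = predict_periods(THETA, PROTOCOL, s10)
        np.testing.assert_allclose(M10, 10 * M1, rtol=1e-12)


def small_config(**fixed):
    grids = {
        "tau_sr": np.array([1.0, 2.0, 4.0]),
        "U_sr": np.array([0.2, 0.3, 0.4]),
        "tau_ar": np.array([8.0, 12.0, 16.0]),
        "c_ar": np.array([0.0025, 0.005, 0.01]),
        "tau_d": np.array([20.0, 30.0, 45.0]),
        "U_max": np.array([0.25, 0.5, 1.0]),
    }
    for k in fixed:
        grids.pop(k)
    return FitConfig(grids=grids, protocol=PROTOCOL, fixed=fixed, n_sp=10)


class TestGridSearch:
    def test_recovers_grid_point_truth_from_noiseless_data(self):
        """Data generated by the deterministic model at an on-grid theta is
        recovered exactly (up to the U_max*U_ar product redundancy)."""
        s_dummy = summary_from(np.ones((2, 10)), np.ones((2, 10)))
        M_true, _ = predict_periods(THETA, PROTOCOL, s_dummy, n_sp=10)
        s = summary_from(M_true, 0.05 * np.abs(M_true) + 0.01)
        config = small_config()
        result = grid_search(s, config)
        for p in ("tau_sr", "U_sr", "tau_ar", "tau_d"):
            assert result.theta[p] == pytest.approx(THETA[p])
        assert result.theta["c_ar"] == pytest.approx(
            THETA["U_ar"] * THETA["U_max"])

    def test_argmax_is_exhaustive(self):
        s = summary_from(np.arange(20, dtype=float).reshape(2, 10) + 1,
                         np.ones((2, 10)))
        result = grid_search(s, small_config())
        assert result.log_l == pytest.approx(result.grid_log_l.max())
        assert np.argmax(result.grid_log_l) == np.flatnonzero(
            result.grid_log_l == result.grid_log_l.max())[0]

    def test_fixed_parameters_respected(self):
        s = summary_from(np.arange(20, dtype=float).reshape(2, 10) + 1,
                         np.ones((2, 10)))
        result = grid_search(s, small_config(U_max=1.0))
        assert result.theta["U_max"] == 1.0


class TestConfidenceIntervals:
    def test_quadratic_loglik_halfwidth_closed_form(self, monkeypatch):
        """With an (artificial) forward model giving
        logL = -(x-a)^2/(2 s^2), the 90%-likelihood interval has the
        closed-form half-width s*sqrt(-2 ln 0.9) around a."""
        a, s_ = 2.0, 0.3
        import sarsyn.fit as fitmod

        def fake_sim(theta, protocol, U0=0.0):
            x = np.atleast_1d(np.asarray(theta["tau_sr"], dtype=float))
            d = (x - a) / s_ / math.sqrt(2.0)
            out = np.ones((len(x), 2, 10))
            out[:, 0, 0] = 1.0 + d  # two opposite residuals keep the total
            out[:, 0, 1] = 1.0 - d  # fixed, so A-normalisation is neutral
            return out

        monkeypatch.setattr(fitmod, "_sim_grid_periods", fake_sim)
        summary = summary_from(np.ones((2, 10)), np.ones((2, 10)))
        fixed = {p: THETA[p] for p in ("U_sr", "tau_ar", "tau_d", "U_max")}
        fixed["c_ar"] = 0.005
        config = FitConfig(grids={"tau_sr": np.linspace(0, 4, 41)},
                           protocol=PROTOCOL, fixed=fixed, n_sp=10)
        result = fitmod.grid_search(summary, config)
        assert result.theta["tau_sr"] == pytest.approx(a, abs=0.05)
        ci = fitmod.confidence_intervals(summary, result, refine_factor=50)
        lo, hi, open_lo, open_hi = ci["tau_sr"]
        half = s_ * math.sqrt(-2.0 * math.log(0.9))
        assert hi - lo == pytest.approx(2 * half, rel=0.05)
        assert not open_lo and not open_hi
        assert lo <= result.theta["tau_sr"] <= hi

    def test_interval_contains_estimate_and_flags_flat_dimension(self):
        s = summary_from(np.arange(20, dtype=float).reshape(2, 10) + 1,
                         np.full((2, 10), 5000.0))  # huge sigma: flat likelihood
        result = grid_search(s, small_config())
        ci = confidence_intervals(s, result, refine_factor=5)
        for p, (lo, hi, open_lo, open_hi) in ci.items():
            assert lo <= result.theta[p] <= hi
            assert open_lo and open_hi  # flat: interval spans the whole scan


class TestQuantumSize:
    def test_poisson_quanta_recover_amplitude(self, rng):
        """Pure Poisson quanta of amplitude s: Fano slope -> s."""
        s_amp, dt = 10.0, 0.05
        lam = 0.004  # events per bin
        counts = rng.poisson(lam, size=(400, 6000))
        segments = counts * (s_amp / dt)  # scaled rate with quantal area s_amp
        res = quantum_size(segments, dt)
        assert res.x0_tilde == pytest.approx(s_amp, rel=0.1)

    def test_scale_equivariance(self, rng):
        segments = rng.poisson(0.01, size=(30, 4000)) * 100.0
        r1 = quantum_size(segments, 0.05)
        r2 = quantum_size(2 * segments, 0.05)
        assert r2.x0_tilde == pytest.approx(2 * r1.x0_tilde, rel=1e-12)

    def test_consistency_improves_with_trials(self):
        """Estimator error shrinks as the trial count grows (10 vs 100)."""
        s_amp, dt, lam = 10.0, 0.05, 0.005
        errs = {10: [], 100: []}
        for n in errs:
            for seed in range(12):
                rng = np.random.default_rng(1000 + seed)
                segs = rng.poisson(lam, size=(n, 4000)) * (s_amp / dt)
                errs[n].append(abs(quantum_size(segs, dt).x0_tilde - s_amp))
        assert np.mean(errs[100]) < np.mean(errs[10])

    def test_sar_tail_recovers_quantal_amplitude(self):
        """Post-train asynchronous release of the stochastic model with
        quantal amplitude A*x0 = 10 pA: Fano regression within 15%."""
        p = SARParams(tau_sr=2, U_sr=0.3, tau_ar=12, U_ar=0.005, U_max=0.5,
                      tau_d=30, N_F=271, x0=1.0)
        spikes = 10.0 * np.arange(25)
        A = 10.0  # pA per transmitter unit -> A*x0 = 10 pA
        ens = simulate_trials(p, spikes, T=300.0, dt=0.05, n_trials=50, seed=21)
        tail_start = int(round((spikes[-1] + 2.0) / 0.05))
        segments = A * ens.q_ar[:, tail_start:] / 0.05  # scaled rate q~ (pA/ms)
        res = quantum_size(segments, 0.05)
        assert res.x0_tilde == pytest.approx(10.0, rel=0.15)

    def test_too_few_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            quantum_size(rng.poisson(0.01, (5, 100)) * 1.0, 0.05)
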