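"""Unit and property tests of the SAR forward model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sarsyn import SARParams, SynapseState, simulate, simulate_trials
from sarsyn.sar_core import (
    decay,
    draw_release_and_replenish,
    on_spike_facilitation,
    snap_spikes,
)


class TestDecay:
    def test_closed_form_single_step(self, fs_pc_params):
        s = SynapseState(u_sr=0.3, u_ar=0.2)
        out = decay(s, 2.0, fs_pc_params)
        assert out.u_sr == pytest.approx(0.3 * math.exp(-1.0))
        assert out.u_ar == pytest.approx(0.2 * math.exp(-2.0 / 12.0))

    def test_matches_fine_euler_integration(self, fs_pc_params):
        # independent route: forward Euler of du/dt = -u/tau at tiny steps
        u, h = 0.3, 1e-5
        for _ in range(int(2.0 / h)):
            u -= h * u / fs_pc_params.tau_sr
        exact = decay(SynapseState(u_sr=0.3), 2.0, fs_pc_params).u_sr
        assert exact == pytest.approx(u, rel=1e-4)

    def test_long_time_rest_states(self):
        p = SARParams(tau_sr=2, U_sr=0.3, tau_ar=12, U_ar=0.005, U_max=0.5,
                      tau_d=30, U0=0.1)
        out = decay(SynapseState(u_sr=0.3, u_ar=0.4), 1e6, p)
        assert out.u_sr == pytest.approx(0.0, abs=1e-12)
        assert out.u_ar == pytest.approx(0.1)  # spontaneous floor U0


class TestFacilitation:
    def test_jump_from_rest(self, fs_pc_params):
        out = on_spike_facilitation(SynapseState(u_sr=0.0, u_ar=0.0), fs_pc_params)
        assert out.u_sr == pytest.approx(fs_pc_params.U_sr)
        assert out.u_ar == pytest.approx(fs_pc_params.U_ar * fs_pc_params.U_max)

    def test_saturation_fixed_points(self, fs_pc_params):
        out = on_spike_facilitation(
            SynapseState(u_sr=1.0, u_ar=fs_pc_params.U_max), fs_pc_params
        )
        assert out.u_sr == pytest.approx(1.0)
        assert out.u_ar == pytest.approx(fs_pc_params.U_max)


class TestStochasticDraws:
    def test_empty_pool_releases_nothing(self, fs_pc_params, rng):
        s = SynapseState(u_sr=0.5, u_ar=0.4, N=0)
        rs = [draw_release_and_replenish(s, True, 0.05, fs_pc_params, rng)
              for _ in range(200)]
        assert all(n_sr == 0 and n_ar == 0 for _, n_sr, n_ar, _ in rs)
        assert any(r > 0 for *_, r in rs)  # replenishment from the empty pool

    def test_no_async_when_rate_zero(self, fs_pc_params, rng):
        s = SynapseState(u_sr=0.5, u_ar=0.0, N=100)
        for _ in range(50):
            _, _, n_ar, _ = draw_release_and_replenish(s, False, 0.05, fs_pc_params, rng)
            assert n_ar == 0

    def test_sync_draw_binomial_moments(self, fs_pc_params, rng):
        # oracle: exact binomial moments N*p and N*p*(1-p)
        N, p = 271, 0.11
        s = SynapseState(u_sr=p, u_ar=0.0, N=N)
        draws = np.array([
            draw_release_and_replenish(s, True, 0.05, fs_pc_params, rng)[1]
            for _ in range(100_000)
        ])
        assert draws.mean() == pytest.approx(N * p, rel=0.01)  # 29.81
        assert draws.var() == pytest.approx(N * p * (1 - p), rel=0.03)  # 26.53

    def test_invalid_bin_width_rejected(self, fs_pc_params, rng):
        s = SynapseState(u_sr=0.1, u_ar=0.1, N=10)
        with pytest.raises(ValueError):
            draw_release_and_replenish(s, False, 3.0 * fs_pc_params.U_max ** -1,
                                       fs_pc_params, rng)


class TestSpikeSnapping:
    def test_snaps_to_nearest_bin(self):
        assert snap_spikes([0.0, 10.02], 0.05, 1000).tolist() == [0, 200]

    def test_rejects_off_grid_and_out_of_range(self):
        with pytest.raises(ValueError):
            snap_spikes([0.0, 10.0], 0.05, 100)  # 10 ms beyond 5 ms span
        with pytest.raises(ValueError):
            snap_spikes([5.0, 4.0], 0.05, 1000)  # unsorted


class TestSimulate:
    def test_rest_is_absorbing_without_spikes(self, fs_pc_params):
        tr = simulate(fs_pc_params, [], T=50, dt=0.05, mode="stochastic", seed=0)
        assert not tr.q_sr.any() and not tr.q_ar.any()
        assert np.all(tr.N == fs_pc_params.N_F)

    def test_spontaneous_release_with_positive_floor(self):
        p = SARParams(tau_sr=2, U_sr=0.3, tau_ar=12, U_ar=0.005, U_max=0.5,
                      tau_d=30, N_F=271, U0=0.01)
        tr = simulate(p, [], T=200, dt=0.05, mode="stochastic", seed=0)
        assert tr.q_ar.sum() > 0  # spontaneous events without any spike

    def test_facilitation_and_depression_shapes(self, fs_pc_params, spikes_100hz):
        """5 spikes at 100 Hz: u_sr relaxes almost fully between spikes,
        u_ar accumulates across the train, the pool depletes."""
        tr = simulate(fs_pc_params, spikes_100hz, T=100, dt=0.05,
                      mode="deterministic")
        sb = tr.spike_bins
        # u_sr just before each later spike is near 0 (tau_sr=2 << 10 ms ISI)
        assert np.all(tr.u_sr[sb[1:] - 1] < 0.05 * fs_pc_params.U_sr / (1 - fs_pc_params.U_sr))
        # u_ar at spikes strictly increases across the train
        assert np.all(np.diff(tr.u_ar[sb]) > 0)
        # pool fraction declines over the train
        assert tr.x[sb[-1]] < tr.x[sb[0]]

    def test_pool_conservation_ledger(self, fs_pc_params, spikes_100hz):
        tr = simulate(fs_pc_params, spikes_100hz, T=100, dt=0.05,
                      mode="stochastic", seed=7)
        lhs = tr.N[1:]
        rhs = tr.N[:-1] - tr.n_sr[:-1] - tr.n_ar[:-1] + tr.r[:-1]
        assert np.array_equal(lhs, rhs)
        assert tr.N.min() >= 0 and tr.N.max() <= fs_pc_params.N_F

    def test_two_spike_facilitation_closed_form(self, fs_pc_params):
        """u_ar just after the 2nd spike has the closed form
        U_ar*U_max*(1 + (1-U_ar)*exp(-(t2-t1)/tau_ar))."""
        t1, t2 = 5.0, 17.0
        tr = simulate(fs_pc_params, [t1, t2], T=30, dt=0.05, mode="deterministic")
        p = fs_pc_params
        expected = p.U_ar * p.U_max * (1 + (1 - p.U_ar) * math.exp(-(t2 - t1) / p.tau_ar))
        got = tr.u_ar[tr.spike_bins[1]]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_classical_stp_limit(self, spikes_100hz):
        """With U_ar = 0 the deterministic mode reduces to the classical
        depressing/facilitating STP model: per-spike release u(t+)*x(t-)
        matches an event-based closed-form STP recursion to machine precision."""
        p = SARParams(tau_sr=2.0, U_sr=0.3, tau_ar=12.0, U_ar=0.0,
                      U_max=0.5, tau_d=30.0, N_F=271, x0=1.0)
        tr = simulate(p, spikes_100hz, T=100, dt=0.05, mode="deterministic")
        # independent oracle: exact event-based STP recursion between spikes
        u, x = 0.0, p.X_F
        expected = []
        prev = None
        for t in spikes_100hz:
            if prev is not None:
                dt_int = t - prev
                u *= math.exp(-dt_int / p.tau_sr)
                x = p.X_F + (x - p.X_F) * math.exp(-dt_int / p.tau_d)
            u = u + p.U_sr * (1 - u)
            q = u * x
            x -= q
            expected.append(q)
            prev = t
        got = tr.q_sr[tr.spike_bins]
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_stochastic_mean_tracks_deterministic(self, fs_pc_params, spikes_100hz):
        det = simulate(fs_pc_params, spikes_100hz, T=100, dt=0.05,
                       mode="deterministic")
        ens = simulate_trials(fs_pc_params, spikes_100hz, T=100, dt=0.05,
                              n_trials=300, seed=3)
        tot = ens.q_sr + ens.q_ar
        # compare 10-ms-window integrals: mean over trials vs deterministic
        w = 200
        stoch = tot.reshape(300, -1, w).sum(axis=2)
        se = stoch.std(axis=0, ddof=1) / math.sqrt(300)
        det_w = det.q_total.reshape(-1, w).sum(axis=1)
        z = np.abs(stoch.mean(axis=0) - det_w) / np.maximum(se, 1e-9)
        assert z.max() < 4.0

    def test_ensemble_matches_single_trial_statistics(self, fs_pc_params, spikes_100hz):
        """Vectorised multi-trial simulation is distributionally consistent
        with repeated single-trial simulation (total release means)."""
        singles = np.array([
            simulate(fs_pc_params, spikes_100hz, T=100, dt=0.05,
                     mode="stochastic", seed=100 + i).q_total.sum()
            for i in range(100)
        ])
        ens = simulate_trials(fs_pc_params, spikes_100hz, T=100, dt=0.05,
                              n_trials=100, seed=9)
        tot = (ens.q_sr + ens.q_ar).sum(axis=1)
        pooled_se = math.sqrt(singles.var(ddof=1) / 100 + tot.var(ddof=1) / 100)
        assert abs(singles.mean() - tot.mean()) < 4 * pooled_se


admissible_params = st.builds(
    SARParams,
    tau_sr=st.floats(0.5, 20),
    U_sr=st.floats(0.0, 1.0),
    tau_ar=st.floats(1.0, 50),
    U_ar=st.floats(0.0, 1.0),
    U_max=st.floats(0.05, 2.0),
    tau_d=st.floats(5.0, 200),
    N_F=st.integers(1, 500),
    x0=st.floats(0.1, 10),
    U0=st.just(0.0),
)


class TestProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(params=admissible_params, seed=st.integers(0, 2**31 - 1),
           n_spikes=st.integers(0, 8))
    def test_bounds_and_pool_conservation(self, params, seed, n_spikes):
        """For any admissible parameters and spike train: u_sr in [0,1],
        u_ar in [U0, U_max], and 0 <= N <= N_F with an exact count ledger."""
        spikes = 5.0 * (1 + np.arange(n_spikes))
        tr = simulate(params, spikes, T=50, dt=0.05, mode="stochastic", seed=seed)
        assert np.all((tr.u_sr >= 0) & (tr.u_sr <= 1 + 1e-12))
        assert np.all((tr.u_ar >= params.U0 - 1e-12) & (tr.u_ar <= params.U_max + 1e-12))
        assert tr.N.min() >= 0 and tr.N.max() <= params.N_F
        drained = tr.n_sr.sum() + tr.n_ar.sum() - tr.r.sum()
        assert tr.N[-1] - tr.n_sr[-1] - tr.n_ar[-1] + tr.r[-1] == params.N_F - drained

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(params=admissible_params)
    def test_deterministic_resource_stays_in_range(self, params):
        spikes = [5.0, 15.0, 25.0]
        tr = simulate(params, spikes, T=50, dt=0.05, mode="deterministic")
        assert np.all(tr.x >= -1e-9)
        assert np.all(tr.x <= params.X_F + 1e-9)
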