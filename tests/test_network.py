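"""Network construction, input protocols and integration."""

import numpy as np
import pytest

from balchaos.network import (
    DivergenceError,
    EIConfig,
    InputProtocol,
    NetworkConfig,
    build_coupling,
    build_ei_coupling,
    input_decomposition,
    make_input,
    phi_autocorr_time_avg,
    simulate,
)


class TestCoupling:
    def test_zero_gain_gives_pure_mean(self):
        cfg = NetworkConfig(N=4, g=0.0, J0=2.0)
        J = build_coupling(cfg, seed=0)
        assert np.all(J.weights == -1.0)  # -J0/sqrt(N) = -2/2

    def test_moments_of_large_matrix(self):
        cfg = NetworkConfig(N=2000, g=2.0, J0=1.0)
        J = build_coupling(cfg, seed=1)
        w = J.weights.ravel()
        n = w.size
        mean_se = cfg.g / np.sqrt(cfg.N) / np.sqrt(n)
        assert abs(w.mean() + 1.0 / np.sqrt(2000)) < 4 * mean_se
        var = w.var()
        var_se = var * np.sqrt(2.0 / n)
        assert abs(var - 4.0 / 2000) < 4 * var_se

    def test_reproducible_per_seed(self):
        cfg = NetworkConfig(N=50, g=1.5)
        a = build_coupling(cfg, seed=42).weights
        b = build_coupling(cfg, seed=42).weights
        assert np.array_equal(a, b)

    def test_k_scaling_affects_effective_scales(self):
        cfg = NetworkConfig(N=1000, g=1.0, J0=1.0, I0=1.0, K=250)
        assert cfg.j0_eff == pytest.approx(0.5)
        assert cfg.i0_eff == pytest.approx(0.5)


class TestEICoupling:
    def test_block_structure_and_degree(self):
        ei = EIConfig(N_E=60, N_I=40, K=10, g=1.6, alpha=0.5)
        J = build_ei_coupling(ei, seed=0)
        W = J.weights.toarray()
        w = ei.block_weights
        # every row: exactly K nonzeros per presynaptic block
        for i in range(ei.N):
            row_e = W[i, : ei.N_E]
            row_i = W[i, ei.N_E :]
            assert (row_e != 0).sum() == ei.K
            assert (row_i != 0).sum() == ei.K
            expect_e = w["EE"] if i < ei.N_E else w["IE"]
            expect_i = w["EI"] if i < ei.N_E else w["II"]
            assert np.all(row_e[row_e != 0] == expect_e)
            assert np.all(row_i[row_i != 0] == expect_i)
        # sign conventions
        assert np.all(W[:, ei.N_E:] <= 0)
        assert np.all(W[:, : ei.N_E] >= 0)

    def test_alpha_zero_silences_excitatory_weights(self):
        ei = EIConfig(N_E=30, N_I=30, K=5, g=1.6, alpha=0.0)
        W = build_ei_coupling(ei, seed=1).weights.toarray()
        assert np.all(W[:, : ei.N_E] == 0)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            EIConfig(N_E=10, N_I=10, K=11, g=1.0, alpha=0.5)

    def test_ei_network_reaches_finite_stationary_rates(self):
        # scaled-down sparse E-I network: stationary, positive rates
        ei = EIConfig(N_E=400, N_I=400, K=80, g=1.6, alpha=0.5)
        J = build_ei_coupling(ei, seed=2)
        traj = simulate(J, ei, InputProtocol(), T=40.0, dt=0.02, seed=3)
        nu = traj.nu()[traj.times >= 20]
        assert np.all(np.isfinite(nu))
        assert nu.mean() > 0.01


class TestInputs:
    def test_common_sin_zero_at_t0_and_identical(self):
        cfg = NetworkConfig(N=16, g=1.0)
        prot = InputProtocol(kind="common_sin", I1=2.0, f=0.25)
        s = make_input(prot, cfg, np.array([0.0, 1.0, 2.0]))
        assert np.all(s[:, 0] == 0.0)
        assert np.all(s == s[0])  # identical across neurons

    def test_independent_phases_frozen_and_uniform(self):
        cfg = NetworkConfig(N=4000, g=1.0)
        prot = InputProtocol(kind="independent_sin", I1=1.0, f=0.1, seed=3)
        ph1 = prot.frozen_phases(cfg.N)
        ph2 = prot.frozen_phases(cfg.N)
        assert np.array_equal(ph1, ph2)
        assert 0 <= ph1.min() and ph1.max() < 2 * np.pi

    def test_independent_population_mean_near_zero(self):
        """Random phases make the population-mean drive O(I1/sqrt(N))."""
        cfg = NetworkConfig(N=5000, g=1.0)
        prot = InputProtocol(kind="independent_sin", I1=1.0, f=0.1, seed=5)
        t = np.linspace(0, 20, 401)
        s = make_input(prot, cfg, t)
        rms = np.sqrt(np.mean(s.mean(axis=0) ** 2))
        assert rms <= 3.0 * prot.I1 / np.sqrt(2 * cfg.N)

    def test_ou_stationary_variance(self):
        cfg = NetworkConfig(N=2, g=1.0)
        prot = InputProtocol(kind="common_ou", tau_s=0.5, D=2.0, seed=9)
        t = np.arange(0.0, 5000.0, 0.05)  # 1e4 correlation times
        s = make_input(prot, cfg, t)[0]
        assert s.var() == pytest.approx(prot.D * prot.tau_s, rel=0.05)

    def test_ou_requires_positive_tau_s(self):
        with pytest.raises(ValueError):
            InputProtocol(kind="common_ou", tau_s=0.0, D=1.0)


class TestSimulate:
    def test_uncoupled_network_matches_scalar_ode(self):
        """g = J0 = 0: h(t) = sqrt(N) I0 (1 - exp(-t/tau)) exactly."""
        cfg = NetworkConfig(N=10, g=0.0, J0=0.0, I0=1.0)
        J = build_coupling(cfg, seed=0)
        traj = simulate(J, cfg, InputProtocol(), T=5.0, dt=0.01,
                        h0=np.zeros(10), store_stride=50)
        expected = np.sqrt(10) * (1 - np.exp(-traj.times))
        assert np.max(np.abs(traj.h - expected[None, :])) < 1e-4

    def test_silenced_network_has_zero_rates(self):
        cfg = NetworkConfig(N=100, g=2.0, J0=1.0, I0=-1.0)
        J = build_coupling(cfg, seed=1)
        traj = simulate(J, cfg, InputProtocol(), T=20.0, dt=0.02, seed=2)
        late = traj.times >= 10.0
        assert np.all(traj.rates()[:, late] == 0.0)
        # currents decay toward -sqrt(N)
        assert traj.h[:, -1] == pytest.approx(-np.sqrt(100), rel=1e-3)

    def test_balance_equation_and_n_scaling(self):
        """mean rate -> I0/J0 with O(1/sqrt(N)) deviations."""
        devs = {}
        for N in (500, 2000):
            cfg = NetworkConfig(N=N, g=2.0, J0=1.0, I0=1.0)
            J = build_coupling(cfg, seed=3)
            traj = simulate(J, cfg, InputProtocol(), T=50.0, dt=0.02, seed=4)
            nu = traj.nu()[traj.times >= 20].mean()
            devs[N] = abs(nu - 1.0)
        assert devs[2000] < 0.1
        # deviation shrinks with N consistently with a 1/sqrt(N) envelope
        assert devs[2000] < devs[500] * np.sqrt(2000 / 500) * 1.5

    def test_divergence_raises(self):
        # runaway positive feedback: large positive mean coupling via J0<0
        cfg = NetworkConfig(N=50, g=0.0, J0=0.0, I0=0.0, transfer="linear")
        J = build_coupling(cfg, seed=0)
        J.weights = np.full((50, 50), 0.5)  # spectral radius 25 >> 1
        with pytest.raises(DivergenceError):
            simulate(J, cfg, InputProtocol(), T=50.0, dt=0.02,
                     h0=np.ones(50), seed=0)

    def test_dt_bound_enforced(self):
        cfg = NetworkConfig(N=10, g=1.0)
        J = build_coupling(cfg, seed=0)
        with pytest.raises(ValueError):
            simulate(J, cfg, InputProtocol(), T=1.0, dt=0.2)

    def test_step_halving_stability(self):
        """Halving dt changes the time-averaged rate by < 1%."""
        cfg = NetworkConfig(N=500, g=2.0)
        J = build_coupling(cfg, seed=5)
        nus = []
        for dt in (0.04, 0.02):
            traj = simulate(J, cfg, InputProtocol(), T=60.0, dt=dt,
                            h0=np.zeros(500), store_stride=int(0.2 / dt))
            nus.append(traj.nu()[traj.times >= 20].mean())
        assert abs(nus[0] - nus[1]) / nus[1] < 0.01


class TestDecomposition:
    def test_residual_identity(self):
        cfg = NetworkConfig(N=200, g=1.5)
        J = build_coupling(cfg, seed=6)
        prot = InputProtocol(kind="common_sin", I1=5.0, f=0.1)
        traj = simulate(J, cfg, prot, T=20.0, dt=0.01, seed=7, store_stride=1)
        dec = input_decomposition(traj, J)
        # central-difference bookkeeping identity, O(dt^2) accurate
        rhs_scale = np.sqrt(np.mean(dec["recurrent"] ** 2))
        resid = np.abs(dec["residual"][:, 2:-2]).max()
        assert resid < 1e-2 * rhs_scale

    def test_common_input_anticorrelated_with_recurrent_feedback(self):
        """Balanced cancellation: population-mean recurrent input tracks
        -dI(t) for slow common drive."""
        cfg = NetworkConfig(N=1000, g=2.0)
        J = build_coupling(cfg, seed=8)
        prot = InputProtocol(kind="common_sin", I1=6.0, f=0.02)
        traj = simulate(J, cfg, prot, T=120.0, dt=0.02, seed=9, store_stride=10)
        dec = input_decomposition(traj, J)
        sel = traj.times >= 20
        dI = make_input(prot, cfg, traj.times)[0]
        rec = dec["recurrent_mean"]
        r = np.corrcoef(rec[sel] - rec[sel].mean(), dI[sel])[0, 1]
        assert r <= -0.8

    def test_independent_input_not_cancelled(self):
        cfg = NetworkConfig(N=1000, g=2.0)
        J = build_coupling(cfg, seed=10)
        prot = InputProtocol(kind="independent_sin", I1=6.0, f=0.02, seed=11)
        traj = simulate(J, cfg, prot, T=120.0, dt=0.02, seed=12, store_stride=10)
        dec = input_decomposition(traj, J)
        sel = traj.times >= 20
        dI = make_input(prot, cfg, traj.times)
        rec = dec["recurrent_mean"][sel]
        for i in (0, 1, 2):
            r = np.corrcoef(rec - rec.mean(), dI[i, sel])[0, 1]
            assert abs(r) <= 0.2


class TestAutocorr:
    def test_lag_zero_is_mean_square_rate(self):
        cfg = NetworkConfig(N=300, g=2.0)
        J = build_coupling(cfg, seed=13)
        traj = simulate(J, cfg, InputProtocol(), T=40.0, dt=0.02, seed=14)
        lags, cb = phi_autocorr_time_avg(traj, 5.0, t_start=15.0, t_span=20.0)
        sel = (traj.times >= 15.0) & (traj.times < 35.0)
        R = traj.rates()[:, sel]
        assert cb[0] == pytest.approx((R**2).mean(), rel=1e-10)
        assert lags[0] == 0.0

    def test_window_shorter_than_lag_rejected(self):
        cfg = NetworkConfig(N=50, g=1.0)
        J = build_coupling(cfg, seed=15)
        traj = simulate(J, cfg, InputProtocol(), T=5.0, dt=0.02, seed=16)
        with pytest.raises(ValueError):
            phi_autocorr_time_avg(traj, 10.0)
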