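"""Non-stationary mean-field grid solver: limits, invariants, oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from balchaos.dmft import (
    DMFTGrid,
    GridSpec,
    dmft_autocorr,
    mc_single_site_oracle,
    solve_mcr,
    solve_tangent,
)
from balchaos.network import InputProtocol, NetworkConfig

COARSE = GridSpec(dt=0.05, transient=10.0, duration=15.0)


def _dummy_grid(duration=40.0, dt=0.05, f=0.0):
    cfg = NetworkConfig(N=1000, g=1.0)
    spec = GridSpec(dt=dt, transient=0.0, duration=duration)
    times = spec.times()
    n = len(times)
    kind = "common_sin" if f > 0 else "none"
    return DMFTGrid(times, np.zeros(n), np.zeros(n), np.zeros((n, n)), cfg,
                    InputProtocol(kind=kind, I1=0.0 if f == 0 else 1.0, f=f), spec)


class TestMeanEquation:
    def test_zero_gain_reduces_to_scalar_ode(self):
        """g = 0: no fluctuations, m follows the deterministic mean ODE."""
        cfg = NetworkConfig(N=900, g=0.0, J0=1.0, I0=1.0)
        prot = InputProtocol(kind="common_sin", I1=3.0, f=0.1)
        grid = GridSpec(dt=0.02, transient=5.0, duration=10.0)
        sol = solve_mcr(cfg, prot, grid)
        assert np.max(np.abs(sol.c)) < 1e-12
        sN = np.sqrt(900)

        def rhs(t, y):
            return -y + sN * (1.0 - max(y[0], 0.0)) + 3.0 * np.sin(2 * np.pi * 0.1 * t)

        ref = solve_ivp(rhs, (0, sol.times[-1]), [0.0], t_eval=sol.times,
                        rtol=1e-10, atol=1e-12)
        # skip the first 2 tau: the balance onset is stiff (rate ~ sqrt(N)/tau)
        # and dominated by the explicit scheme's startup error
        late = sol.times >= 2.0
        assert np.max(np.abs(sol.m - ref.y[0])[late]) < 1e-3

    def test_balance_rate_autonomous(self):
        cfg = NetworkConfig(N=2000, g=2.0)
        sol = solve_mcr(cfg, InputProtocol(), COARSE)
        assert sol.nu[-1] == pytest.approx(1.0, abs=0.06)


class TestGridInvariants:
    def test_symmetry_and_psd(self):
        cfg = NetworkConfig(N=2000, g=2.0)
        sol = solve_mcr(cfg, InputProtocol(), COARSE)
        assert np.array_equal(sol.c, sol.c.T)
        w = np.linalg.eigvalsh(sol.c)
        assert w.min() >= -1e-6 * sol.c.max()

    def test_reparametrisation_invariance(self):
        """(N, J0, I0) enters only through sqrt(N) J0 and sqrt(N) I0."""
        g = 2.0
        a = solve_mcr(NetworkConfig(N=1600, g=g, J0=1.0, I0=1.0),
                      InputProtocol(), COARSE)
        scale = np.sqrt(1600 / 400)
        b = solve_mcr(NetworkConfig(N=400, g=g, J0=scale, I0=scale),
                      InputProtocol(), COARSE)
        assert np.allclose(a.m, b.m, atol=1e-12)
        assert np.allclose(a.c, b.c, atol=1e-12)

    def test_cyclostationarity(self):
        """After the transient, m and c repeat at the drive period."""
        cfg = NetworkConfig(N=1600, g=2.0)
        f = 0.1
        prot = InputProtocol(kind="common_sin", I1=0.5 * np.sqrt(1600), f=f)
        grid = GridSpec(dt=0.05, transient=20.0, duration=30.0)
        sol = solve_mcr(cfg, prot, grid)
        p = int(round(1.0 / f / grid.dt))
        n0 = sol.n_transient + p
        mdiff = np.abs(sol.m[n0 + p:] - sol.m[n0:-p]).max()
        assert mdiff < 0.01 * np.abs(sol.m[n0:]).max()
        d0 = np.diag(sol.c)
        cdiff = np.abs(d0[n0 + p:] - d0[n0:-p]).max()
        assert cdiff < 0.01 * d0[n0:].max()

    def test_grid_refinement_convergence(self):
        cfg = NetworkConfig(N=1000, g=2.0)
        lams, nus = [], []
        for dt in (0.04, 0.02):
            sol = solve_mcr(cfg, InputProtocol(),
                            GridSpec(dt=dt, transient=10.0, duration=20.0))
            lams.append(solve_tangent(sol).lambda1)
            nus.append(sol.nu[-1])
        assert abs(lams[0] - lams[1]) < 0.01
        assert abs(nus[0] - nus[1]) / nus[1] < 0.01

    def test_divergence_error_on_instability(self):
        # gain far above the global stability bound
        cfg = NetworkConfig(N=1000, g=8.0)
        with pytest.raises(RuntimeError, match="instability"):
            solve_mcr(cfg, InputProtocol(), GridSpec(dt=0.05, transient=20.0,
                                                     duration=40.0))


class TestTangent:
    @pytest.mark.parametrize("q0", [0.25, 1.0, 4.0])
    def test_constant_kernel_closed_form(self, q0):
        """(tau lambda + 1)^2 = q0 for a constant source kernel."""
        gridsol = _dummy_grid()

        def kern(sl, n):
            return np.full(len(np.arange(sl.start or 0, sl.stop)), q0)

        tg = solve_tangent(gridsol, kernel=kern)
        assert tg.lambda1 == pytest.approx(np.sqrt(q0) - 1.0, abs=1e-3)

    def test_silenced_network_exponent(self):
        """Negative total input: rates zero, q' = 0, lambda_1 = -1/tau."""
        cfg = NetworkConfig(N=900, g=2.0, I0=-1.0)
        sol = solve_mcr(cfg, InputProtocol(), COARSE)
        assert np.all(sol.m[5:] < 0)
        tg = solve_tangent(sol)
        assert tg.lambda1 == pytest.approx(-1.0, abs=1e-6)

    def test_nonpositive_kernel_diag_error(self):
        gridsol = _dummy_grid(duration=5.0)

        def kern(sl, n):
            # strong negative source drives k(t,t) through zero
            return np.full(len(np.arange(sl.start or 0, sl.stop)), -200.0)

        with pytest.raises(RuntimeError, match="non-positive"):
            solve_tangent(gridsol, kernel=kern)


class TestFrozenOUDrive:
    def test_common_ou_realisation_integrates(self):
        """One frozen Ornstein-Uhlenbeck realisation as common drive: the
        solver stays finite and reproducible per drive seed."""
        cfg = NetworkConfig(N=900, g=1.8)
        prot = InputProtocol(kind="common_ou", tau_s=2.0, D=50.0, seed=4)
        grid = GridSpec(dt=0.05, transient=5.0, duration=10.0)
        a = solve_mcr(cfg, prot, grid)
        b = solve_mcr(cfg, prot, grid)
        assert np.array_equal(a.m, b.m)
        assert np.all(np.isfinite(a.c))
        # the drive realisation actually moves the mean current
        assert np.std(a.m[a.n_transient:]) > 0.05

    def test_independent_drive_rejected(self):
        cfg = NetworkConfig(N=900, g=1.8)
        with pytest.raises(ValueError, match="common"):
            solve_mcr(cfg, InputProtocol(kind="independent_sin", I1=1.0,
                                         f=0.1),
                      GridSpec(dt=0.05, transient=2.0, duration=4.0))


class TestAutocorr:
    def test_even_and_definition(self):
        cfg = NetworkConfig(N=1000, g=2.0)
        sol = solve_mcr(cfg, InputProtocol(), COARSE)
        lags, cb = dmft_autocorr(sol, 5.0, t_span=8.0)
        assert lags[0] == 0.0
        # lag-0 equals the second moment of the rate on the diagonal over
        # the t' window
        from balchaos.gauss_moments import relu_cross_grid
        n0 = sol.n_transient
        n_win = int(round(8.0 / sol.grid.dt))
        sl = slice(n0, n0 + n_win)
        cd = np.diag(sol.c)
        diag_vals = relu_cross_grid(sol.m[sl], sol.m[sl], cd[sl], cd[sl],
                                    cd[sl])
        assert cb[0] == pytest.approx(diag_vals.mean(), rel=1e-10)

    def test_span_too_short_rejected(self):
        cfg = NetworkConfig(N=1000, g=2.0)
        sol = solve_mcr(cfg, InputProtocol(), COARSE)
        with pytest.raises(ValueError):
            dmft_autocorr(sol, 100.0)


class TestSingleSiteOracle:
    def test_zero_gain_no_fluctuations(self):
        cfg = NetworkConfig(N=900, g=0.0)
        out = mc_single_site_oracle(cfg, InputProtocol(),
                                    GridSpec(dt=0.05, transient=2.0, duration=5.0),
                                    M=500, iterations=4, seed=0)
        assert np.max(np.abs(out["c"])) < 1e-12

    def test_deterministic_per_seed(self):
        cfg = NetworkConfig(N=900, g=1.5)
        grid = GridSpec(dt=0.1, transient=2.0, duration=4.0)
        a = mc_single_site_oracle(cfg, InputProtocol(), grid, M=300,
                                  iterations=3, seed=5)
        b = mc_single_site_oracle(cfg, InputProtocol(), grid, M=300,
                                  iterations=3, seed=5)
        assert np.array_equal(a["c"], b["c"])

    def test_matches_grid_solver(self):
        """Sampled single-site paths reproduce the deterministic grid c."""
        cfg = NetworkConfig(N=1600, g=2.0)
        prot = InputProtocol(kind="common_sin", I1=0.4 * 40.0, f=0.1)
        grid = GridSpec(dt=0.05, transient=5.0, duration=10.0)
        det = solve_mcr(cfg, prot, grid)
        mc = mc_single_site_oracle(cfg, prot, grid, M=4000, iterations=15,
                                   seed=1)
        # 4 MC standard errors plus a small floor for the finite-M bias of
        # the self-consistent iteration (q is re-estimated from the sampled
        # paths, so its noise feeds back nonlinearly)
        err = np.abs(mc["c"] - det.c)
        tol = 4.0 * mc["c_se"] + 0.015 * det.c.max()
        frac_bad = np.mean(err > tol)
        assert frac_bad < 0.01
        assert err.max() < 0.1 * det.c.max()
        assert np.max(np.abs(mc["m"] - det.m)) < 0.15
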