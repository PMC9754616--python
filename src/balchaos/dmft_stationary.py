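"""Stationary dynamic mean-field theory.

For the autonomous balanced network (constant input) and for independent
sinusoidal drive, the single-site statistics are stationary: a constant
mean current m and a lag-dependent residual autocorrelation c(lag).  The
stationary limit of the two-time equations is the second-order relation

    (1 - tau^2 d^2/dlag^2) c(lag) = q(lag),

solved as a damped fixed-point iteration in Fourier space
(c_hat = q_hat / (1 + (tau w)^2)) on a periodic lag grid, jointly with the
balance condition 0 = -m - sqrt(N) J0 nu + sqrt(N) I0.

Independent sinusoidal drive with random phases adds, after low-pass
filtering by the leak, a deterministic per-neuron component of amplitude
A = I1 / sqrt(1 + (2 pi f tau)^2) and uniform phase.  The phase is handled
by explicit quadrature (periodic midpoint rule), the residual Gaussian
part self-consistently as above.

The largest Lyapunov exponent reuses the two-time tangent machinery of
:mod:`balchaos.dmft` with the stationary kernel embedded on a grid, so the
stationary and non-stationary code paths share one exponent extractor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from balchaos.dmft import DMFTGrid, GridSpec, solve_tangent
from balchaos.gauss_moments import relu_cross_grid, relu_mean, step_cross_grid
from balchaos.network import InputProtocol, NetworkConfig

__all__ = [
    "StationarySolution",
    "solve_autonomous",
    "solve_independent_drive",
    "lambda1_const",
    "stationary_phi_autocorr",
]

_N_THETA = 32


@dataclass
class StationarySolution:
    """Self-consistent stationary order parameters.

    ``c_resid`` is the Gaussian residual autocorrelation c^(lag); the total
    current autocorrelation adds the filtered-drive component
    (A^2/2) cos(2 pi f lag) for independent sinusoidal input.
    """

    m: float
    lags: np.ndarray
    c_resid: np.ndarray
    nu: float
    A: float
    lambda1: float
    f: float
    config: NetworkConfig
    iterations: int
    residual: float

    @property
    def c0(self) -> float:
        return float(self.c_resid[0])

    def c_total(self) -> np.ndarray:
        return self.c_resid + 0.5 * self.A**2 * np.cos(2 * np.pi * self.f * self.lags)


def _theta_nodes(n: int = _N_THETA) -> np.ndarray:
    return 2.0 * np.pi * (np.arange(n) + 0.5) / n


def _solve_mean(config: NetworkConfig, nu_of_m) -> float:
    """Root of the stationary balance condition -m + sqrt(N)(I0 - J0 nu(m))."""
    sN = np.sqrt(config.N)
    j0, i0 = config.j0_eff, config.i0_eff

    def G(m):
        return -m + sN * (i0 - j0 * nu_of_m(m))

    a = 10.0 * (1.0 + sN * abs(i0))
    return brentq(G, -a, a, xtol=1e-12, rtol=1e-14)


def _lag_grid(tau: float, span: float, n_lags: int, f: float):
    """Periodic lag grid; the span is rounded up to whole drive periods so
    that the drive is commensurate with the circular domain."""
    if f > 0:
        period = 1.0 / f
        n_per = max(1, int(np.ceil(span / period)))
        span = n_per * period
    dlag = span / n_lags
    k = np.arange(n_lags)
    lags_abs = dlag * np.minimum(k, n_lags - k)  # circular |lag|
    omega = 2.0 * np.pi * np.fft.rfftfreq(n_lags, d=dlag)
    filt = 1.0 / (1.0 + (tau * omega) ** 2)
    return lags_abs, dlag, filt


def _embed_lambda1(
    config: NetworkConfig,
    m: float,
    qprime_lags: np.ndarray,
    lags_abs: np.ndarray,
    f: float,
    emb: Optional[GridSpec] = None,
) -> float:
    """lambda_1 from the two-time tangent solver with a stationary kernel."""
    if emb is None:
        dur = 40.0 * config.tau
        if f > 0:
            period = 1.0 / f
            dur = max(dur, 4 * period)
        emb = GridSpec(dt=0.05 * config.tau, transient=0.0, duration=dur)
    times = emb.times(config.tau)
    n_t = len(times)
    # kernel value as a function of |t - s|, interpolated from the lag grid;
    # beyond the grid's half-span the kernel has settled to its asymptotic
    # form, which for periodic drive is a persistent oscillation at the
    # drive period -- extend the last whole period periodically (a constant
    # clamp would freeze the oscillation at an arbitrary phase)
    order = np.argsort(lags_abs)
    lag_sorted = lags_abs[order]
    qp_sorted = qprime_lags[order]
    diffs = times - times[0]
    lag_max = lag_sorted[-1]
    if f > 0 and 1.0 / f < lag_max:
        period = 1.0 / f
        base = lag_max - period
        diffs = np.where(diffs <= lag_max,
                         diffs, base + np.mod(diffs - base, period))
    qp_of_diff = np.interp(diffs, lag_sorted, qp_sorted)

    dummy = DMFTGrid(
        times=times,
        m=np.full(n_t, m),
        nu=np.zeros(n_t),
        c=np.zeros((n_t, n_t)),
        config=config,
        protocol=InputProtocol(kind="independent_sin" if f > 0 else "none",
                               I1=0.0, f=f),
        grid=emb,
    )

    def kernel(i_sl, n):
        j = np.arange(i_sl.start or 0, i_sl.stop)
        return qp_of_diff[np.abs(j - n)]

    tg = solve_tangent(dummy, kernel=kernel)
    return tg.lambda1


def solve_autonomous(
    config: NetworkConfig,
    n_lags: int = 1024,
    span: float = 50.0,
    tol: float = 1e-8,
    max_iter: int = 4000,
    damping: float = 0.7,
    c_init: Optional[np.ndarray] = None,
    compute_lambda1: bool = True,
    emb: Optional[GridSpec] = None,
) -> StationarySolution:
    """Stationary solution for constant external input.

    Fixed-point regime (g < sqrt(2)): c(lag) converges to a flat profile
    (frozen heterogeneous currents).  Chaotic regime: c decays with the
    lag.  lambda_1 is obtained by embedding the stationary kernel in the
    two-time tangent solver.
    """
    return _solve_stationary(config, I1=0.0, f=0.0, n_lags=n_lags, span=span,
                             tol=tol, max_iter=max_iter, damping=damping,
                             c_init=c_init, compute_lambda1=compute_lambda1,
                             emb=emb)


def solve_independent_drive(
    config: NetworkConfig,
    protocol: InputProtocol,
    n_lags: int = 1024,
    span: float = 50.0,
    tol: float = 1e-8,
    max_iter: int = 4000,
    damping: float = 0.7,
    c_init: Optional[np.ndarray] = None,
    compute_lambda1: bool = True,
    emb: Optional[GridSpec] = None,
) -> StationarySolution:
    """Stationary solution under independent sinusoidal drive."""
    if protocol.kind != "independent_sin":
        raise ValueError("protocol must be independent_sin")
    return _solve_stationary(config, I1=protocol.I1, f=protocol.f, n_lags=n_lags,
                             span=span, tol=tol, max_iter=max_iter,
                             damping=damping, c_init=c_init,
                             compute_lambda1=compute_lambda1, emb=emb)


def _solve_stationary(
    config: NetworkConfig,
    I1: float,
    f: float,
    n_lags: int,
    span: float,
    tol: float,
    max_iter: int,
    damping: float,
    c_init: Optional[np.ndarray],
    compute_lambda1: bool,
    emb: Optional[GridSpec],
) -> StationarySolution:
    if config.transfer != "relu":
        raise ValueError("the stationary solver is specific to the relu transfer")
    tau = config.tau
    g2 = config.g**2
    A = I1 / np.sqrt(1.0 + (2.0 * np.pi * f * tau) ** 2) if f > 0 else float(I1)
    lags_abs, dlag, filt = _lag_grid(tau, span, n_lags, f)
    theta = _theta_nodes()
    # q and c are even in the lag, so only half the circular grid is computed
    k_half = np.arange(n_lags // 2 + 1)
    lags_half = dlag * k_half
    mirror = np.minimum(np.arange(n_lags), n_lags - np.arange(n_lags))
    if A > 0:
        drive1 = A * np.sin(theta)[:, None]  # (theta, 1)
        drive2 = A * np.sin(theta[:, None] - 2.0 * np.pi * f * lags_half[None, :])
    if c_init is not None:
        c = np.array(c_init, dtype=float)
        if c.shape != (n_lags,):
            raise ValueError("c_init has wrong length")
    else:
        nu0 = config.i0_eff / max(config.j0_eff, 1e-12) if config.j0_eff > 0 else 1.0
        c = g2 * max(nu0, 0.5) ** 2 * np.exp(-lags_abs / tau)
    m = 0.0
    it = 0
    diff = np.inf
    for it in range(1, max_iter + 1):
        c0 = max(c[0], 0.0)
        if A > 0:
            def nu_of_m(mm, c0=c0):
                return relu_mean(mm + A * np.sin(theta), c0).mean()
        else:
            def nu_of_m(mm, c0=c0):
                return relu_mean(mm, c0)
        m = _solve_mean(config, nu_of_m)
        cc = np.clip(c[k_half], -c0, c0)
        if A > 0:
            q_th = relu_cross_grid(m + drive1, m + drive2, c0, c0, cc[None, :],
                                   nodes=40)
            q_half = g2 * q_th.mean(axis=0)
        else:
            q_half = g2 * relu_cross_grid(m, m, c0, c0, cc, nodes=40)
        q = q_half[mirror]
        c_new = np.fft.irfft(np.fft.rfft(q) * filt, n_lags)
        diff = np.max(np.abs(c_new - c))
        c = c + damping * (c_new - c)
        if diff < tol * max(1.0, c0):
            break
    else:
        raise RuntimeError(
            f"stationary fixed point did not converge (residual {diff:.2e}); "
            "try smaller g or stronger damping"
        )
    c0 = max(c[0], 0.0)
    if A > 0:
        nu = float(relu_mean(m + A * np.sin(theta), c0).mean())
    else:
        nu = float(relu_mean(m, c0))
    lam = np.nan
    if compute_lambda1:
        cc = np.clip(c[k_half], -c0, c0)
        if A > 0:
            qp_th = step_cross_grid(m + drive1, m + drive2, c0, c0, cc[None, :],
                                    nodes=40)
            qp = g2 * qp_th.mean(axis=0)[mirror]
        else:
            qp = g2 * step_cross_grid(m, m, c0, c0, cc, nodes=40)[mirror]
        lam = _embed_lambda1(config, m, qp, lags_abs, f, emb=emb)
    return StationarySolution(
        m=float(m),
        lags=lags_abs,
        c_resid=c,
        nu=nu,
        A=A,
        lambda1=lam,
        f=f,
        config=config,
        iterations=it,
        residual=float(diff),
    )


def stationary_phi_autocorr(sol: StationarySolution):
    """Time-averaged rate autocorrelation Cbar_phiphi(lag) of the stationary
    solution (phase-averaged for independent drive)."""
    g2 = sol.config.g**2  # noqa: F841
    c0 = sol.c0
    cc = np.clip(sol.c_resid, -c0, c0)
    theta = _theta_nodes()
    if sol.A > 0:
        mu1 = sol.m + sol.A * np.sin(theta)[:, None]
        mu2 = sol.m + sol.A * np.sin(
            theta[:, None] - 2.0 * np.pi * sol.f * sol.lags[None, :]
        )
        vals = relu_cross_grid(mu1, mu2, c0, c0, cc[None, :]).mean(axis=0)
    else:
        vals = relu_cross_grid(sol.m, sol.m, c0, c0, cc)
    return sol.lags, vals


_L1_CACHE: dict = {}


def lambda1_const(
    g: float, I0: float = 1.0, J0: float = 1.0, tau: float = 1.0
) -> float:
    """Largest Lyapunov exponent of the autonomous balanced network.

    By positive homogeneity of the threshold-linear transfer the result is
    independent of the (positive) input scale, so it is a function of g
    alone; computed once per g via :func:`solve_autonomous` on a large-N
    configuration and cached.
    """
    key = (round(float(g), 12), round(float(I0), 12), round(float(J0), 12), tau)
    if key not in _L1_CACHE:
        cfg = NetworkConfig(N=100_000_000, g=g, J0=J0, I0=I0, tau=tau)
        sol = solve_autonomous(cfg)
        _L1_CACHE[key] = sol.lambda1
    return _L1_CACHE[key]
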