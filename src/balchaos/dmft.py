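"""Non-stationary dynamic mean-field theory on a two-time grid.

For common (population-wide) time-varying input, the network statistics are
genuinely non-stationary, so the mean-field order parameters carry explicit
absolute-time dependence.  The closed self-consistent system is

    tau dm/dt      = -m - sqrt(N) J0 nu(t) + sqrt(N) I0 + dI(t),
    tau dc(t,s)/ds = -c(t,s) + r(t,s),
    tau dr(t,s)/dt = -r(t,s) + q(t,s),

where m(t) is the mean current, c(t,s) = <h~(t) h~(s)> the residual
autocorrelation, r(t,s) = <h~(t) eta(s)> an auxiliary cross-correlation,
nu(t) = E[phi(m(t) + h~(t))] the population rate, and
q(t,s) = g^2 E[phi(m(t)+h~(t)) phi(m(s)+h~(s))] a bivariate-Gaussian moment
evaluated with the kernels in :mod:`balchaos.gauss_moments`.

The equations are integrated forward on a uniform two-time grid in
wavefront order with explicit Euler steps: at each new grid time t_{n+1},
the auxiliary column r(., t_n) is integrated upward in its first argument
from r(0, s) = 0 (a first-order linear recurrence, evaluated exactly with
a scan), then c is advanced in s into the new column and mirrored (c is
symmetric by construction).

The tangent (perturbation) kernel k(t,s) obeys the same bidirectional
first-order structure with source kernel
q'(t,s) = g^2 P(m(t)+h~(t) > 0, m(s)+h~(s) > 0), and the largest Lyapunov
exponent is read off the growth of the diagonal k(t,t).  The exponent is
extracted by linear regression of log k(t,t) and inversion of the Euler
scheme's exact dispersion relation (per-step growth rho = 1 - D + D sqrt(q)
for constant kernels, D = grid step / tau), which makes the silenced-network
value -1/tau and the constant-kernel closed form (sqrt(q0)-1)/tau exact at
any step size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.signal import lfilter

from balchaos.gauss_moments import relu_cross_grid, relu_mean, step_cross_grid
from balchaos.network import InputProtocol, NetworkConfig

__all__ = [
    "GridSpec",
    "DMFTGrid",
    "TangentGrid",
    "solve_mcr",
    "solve_tangent",
    "dmft_autocorr",
    "mc_single_site_oracle",
]

_DIVERGENCE_C = 1e6


@dataclass(frozen=True)
class GridSpec:
    """Uniform two-time grid: step ``dt`` (<= 0.05 tau), ``transient``
    discarded from reported statistics, ``duration`` measured after it."""

    dt: float = 0.02
    transient: float = 20.0
    duration: float = 30.0

    def times(self, tau: float = 1.0, max_frac: float = 0.05) -> np.ndarray:
        if self.dt > max_frac * tau:
            raise ValueError(f"grid step must satisfy dt <= {max_frac}*tau")
        n = int(round((self.transient + self.duration) / self.dt))
        return np.arange(n + 1) * self.dt


@dataclass
class DMFTGrid:
    """Solution of the m/c/r system on the two-time grid."""

    times: np.ndarray
    m: np.ndarray
    nu: np.ndarray
    c: np.ndarray  # (T, T), symmetric
    config: NetworkConfig
    protocol: InputProtocol
    grid: GridSpec
    r: Optional[np.ndarray] = field(default=None, repr=False)  # (T, T) if kept

    @property
    def n_transient(self) -> int:
        return int(round(self.grid.transient / self.grid.dt))

    def validate(self, tol: float = 1e-3) -> None:
        cd = np.diag(self.c)
        if np.any(cd < -tol * max(cd.max(), 1e-30)):
            raise RuntimeError("negative diagonal autocorrelation on the grid")
        asym = np.max(np.abs(self.c - self.c.T))
        if asym > tol * max(cd.max(), 1e-30):
            raise RuntimeError(f"c symmetry violated: {asym}")


@dataclass
class TangentGrid:
    """Perturbation kernels and the extracted Lyapunov exponent."""

    lambda1: float
    log_k_diag: np.ndarray
    fit_rsq: float
    fit_slice: tuple
    k: Optional[np.ndarray] = field(default=None, repr=False)
    l: Optional[np.ndarray] = field(default=None, repr=False)


def _common_drive(protocol: InputProtocol, times: np.ndarray) -> np.ndarray:
    """Scalar common drive dI(t) on the grid (one frozen realisation for OU)."""
    if protocol.kind == "none":
        return np.zeros_like(times)
    if protocol.kind == "common_sin":
        return protocol.I1 * np.sin(2.0 * np.pi * protocol.f * times)
    if protocol.kind == "common_ou":
        rng = np.random.default_rng(protocol.seed)
        dt = times[1] - times[0]
        decay = np.exp(-dt / protocol.tau_s)
        sigma = np.sqrt(protocol.D * protocol.tau_s)
        kick = sigma * np.sqrt(max(1.0 - decay**2, 0.0))
        x = sigma * rng.standard_normal()
        out = np.empty_like(times)
        out[0] = x
        for n in range(1, len(times)):
            x = decay * x + kick * rng.standard_normal()
            out[n] = x
        return out
    raise ValueError(
        f"non-stationary DMFT handles common or no drive, got {protocol.kind!r}"
    )


def _scan_column(source: np.ndarray, delta: float) -> np.ndarray:
    """Integrate y_{i+1} = (1-delta) y_i + delta * source_i with y_0 = 0.

    Returns y_0..y_{len(source)} (length len(source)+1).
    """
    y = lfilter([delta], [1.0, -(1.0 - delta)], source)
    out = np.empty(len(source) + 1)
    out[0] = 0.0
    out[1:] = y
    return out


def solve_mcr(
    config: NetworkConfig,
    protocol: InputProtocol = InputProtocol(),
    grid: GridSpec = GridSpec(),
    keep_r: bool = False,
    nodes: int = 80,
) -> DMFTGrid:
    """Forward-integrate the non-stationary mean-field system.

    Initial condition m(0) = 0, c = r = 0 (deterministic zero initial
    residuals); statistics before ``grid.transient`` should be discarded by
    consumers.  At each wavefront n the auxiliary column r(., t_n) is
    rebuilt exactly from its own initial condition r(0, s) = 0 using the
    already-computed column c(., t_n), then the new column c(., t_{n+1}) is
    an Euler step in the second time argument.
    """
    if config.transfer != "relu":
        raise ValueError("the mean-field solver is specific to the relu transfer")
    tau = config.tau
    times = grid.times(tau)
    n_t = len(times)
    dt = grid.dt
    delta = dt / tau
    g2 = config.g**2
    sN = np.sqrt(config.N)
    j0, i0 = config.j0_eff, config.i0_eff
    drive = _common_drive(protocol, times)

    m = np.zeros(n_t)
    nu = np.zeros(n_t)
    c = np.zeros((n_t, n_t))
    r_full = np.zeros((n_t, n_t)) if keep_r else None
    cd = np.zeros(n_t)  # diagonal cache
    for n in range(n_t - 1):
        sl = slice(0, n + 1)
        # q(., t_n) from the current column of c
        q_col = g2 * relu_cross_grid(m[sl], m[n], cd[sl], cd[n], c[sl, n],
                                     nodes=nodes)
        # r(., t_n): exact scan of tau dr/dt = -r + q from r(0, t_n) = 0
        r_col = _scan_column(q_col, delta)  # indices 0..n+1
        if keep_r:
            r_full[: n + 2, n] = r_col
        # c(., t_{n+1}): Euler step in s using r(., t_n)
        c[: n + 1, n + 1] = (1.0 - delta) * c[: n + 1, n] + delta * r_col[: n + 1]
        c[n + 1, : n + 1] = c[: n + 1, n + 1]
        c[n + 1, n + 1] = (1.0 - delta) * c[n + 1, n] + delta * r_col[n + 1]
        cd[n + 1] = c[n + 1, n + 1]
        if cd[n + 1] > _DIVERGENCE_C:
            raise RuntimeError(
                f"global instability: c(t,t) = {cd[n+1]:.3e} at t = {times[n+1]:.2f}"
            )
        nu[n] = relu_mean(m[n], max(cd[n], 0.0))
        m[n + 1] = m[n] + delta * (-m[n] - sN * j0 * nu[n] + sN * i0 + drive[n])
    nu[-1] = relu_mean(m[-1], max(cd[-1], 0.0))
    sol = DMFTGrid(times, m, nu, c, config, protocol, grid, r=r_full)
    sol.validate()
    return sol


def _fit_lambda1(
    logkd: np.ndarray,
    times: np.ndarray,
    delta: float,
    transient_idx: int,
    period: float,
) -> tuple[float, float, tuple]:
    """Regression of log k(t,t) over the final half (whole drive periods),
    then inversion of the scheme's dispersion relation.

    A log-time regressor absorbs the algebraic prefactor of the diagonal
    kernel (k(t,t) ~ t^alpha e^(2 lambda t) asymptotically, a boundary
    effect of the forward integration); without it the fitted slope is
    biased by O(1/t) at the window centre.
    """
    n_t = len(logkd)
    start = max(transient_idx, n_t // 2)
    y_all = logkd
    if period > 0 and np.isfinite(period):
        p_steps = max(1, int(round(period / (times[1] - times[0]))))
        # remove the cyclostationary modulation: centred moving average over
        # exactly one drive period (exact for periodic components, leaves the
        # linear trend unchanged)
        if p_steps > 1 and n_t > 2 * p_steps:
            kern = np.ones(p_steps) / p_steps
            y_all = np.convolve(logkd, kern, mode="valid")
            n_t = len(y_all)
            start = max(transient_idx, n_t // 2)
        n_avail = n_t - start
        n_fit = (n_avail // p_steps) * p_steps
        if n_fit >= p_steps:
            start = n_t - n_fit
    idx = np.arange(start, n_t)
    y = y_all[idx]
    x = idx.astype(float)
    X = np.column_stack([x, np.log(x), np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope = coef[0]
    resid = y - X @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    rsq = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    rho = np.exp(0.5 * slope)  # per-step growth in each time direction
    lam = (rho - 1.0) / delta
    return lam, rsq, (start, n_t)


def solve_tangent(
    gridsol: DMFTGrid,
    kernel: Optional[Callable] = None,
    keep_kernels: bool = False,
    rsq_warn: float = 0.95,
    nodes: int = 80,
) -> TangentGrid:
    """Integrate the tangent kernels k, l on the grid and extract lambda_1.

    ``kernel(i_slice, n)`` -> q'(t_i, t_n) for i in the slice may override
    the source kernel (used for synthetic closed-form checks and for
    stationary embeddings); by default it is g^2 * P(both currents
    positive) evaluated from the grid solution.
    Seeds: k(0,0) = 1, l(0,.) = 0 (so k(0,s) decays as the discrete
    exponential).
    """
    times = gridsol.times
    n_t = len(times)
    dt = gridsol.grid.dt
    tau = gridsol.config.tau
    delta = dt / tau
    g2 = gridsol.config.g**2
    m, c = gridsol.m, gridsol.c
    cd = np.diag(c).copy()

    if kernel is None:
        def kernel(i_sl, n):  # noqa: ANN001
            return g2 * step_cross_grid(m[i_sl], m[n], cd[i_sl], cd[n],
                                        c[i_sl, n], nodes=nodes)

    # only the current column of k is needed (plus the diagonal trace);
    # full kernels are materialised only on request
    k_full = np.zeros((n_t, n_t)) if keep_kernels else None
    l_full = np.zeros((n_t, n_t)) if keep_kernels else None
    k_col = np.zeros(n_t)
    k_col[0] = 1.0
    if keep_kernels:
        k_full[0, 0] = 1.0
    logkd = np.empty(n_t)
    logkd[0] = 0.0
    scale_log = 0.0  # cumulative log of factors removed by rescaling
    for n in range(n_t - 1):
        sl = slice(0, n + 1)
        qp_col = kernel(sl, n)
        # l(., t_n): scan of tau dl/dt = -l + k q' from l(0, t_n) = 0
        l_col = _scan_column(k_col[sl] * qp_col, delta)  # indices 0..n+1
        new_col = np.empty(n_t)
        new_col[sl] = (1.0 - delta) * k_col[sl] + delta * l_col[: n + 1]
        # symmetry: k(t_{n+1}, t_i) = k(t_i, t_{n+1}) gives the entry below
        # the old diagonal, then the new diagonal point
        k_np1_n = new_col[n]
        new_col[n + 1] = (1.0 - delta) * k_np1_n + delta * l_col[n + 1]
        d = new_col[n + 1]
        if d <= 0.0:
            raise RuntimeError(
                f"non-positive diagonal tangent kernel at t = {times[n+1]:.2f}"
            )
        logkd[n + 1] = np.log(d) + scale_log
        if keep_kernels:
            l_full[: n + 2, n] = l_col
            k_full[: n + 2, n + 1] = new_col[: n + 2]
            k_full[n + 1, : n + 2] = new_col[: n + 2]
        k_col = new_col
        if d < 1e-80 or d > 1e80:
            k_col = k_col / d
            scale_log += np.log(d)
    period = gridsol.protocol.period if gridsol.protocol.f > 0 else np.inf
    lam, rsq, fit_slice = _fit_lambda1(
        logkd, times, delta, gridsol.n_transient, period
    )
    if rsq < rsq_warn:
        warnings.warn(
            f"lambda1 fit R^2 = {rsq:.3f} < {rsq_warn}; estimate may be unreliable",
            RuntimeWarning,
        )
    return TangentGrid(
        lambda1=lam * tau,
        log_k_diag=logkd,
        fit_rsq=rsq,
        fit_slice=fit_slice,
        k=k_full,
        l=l_full,
    )


def dmft_autocorr(gridsol: DMFTGrid, max_lag: float, t_span: Optional[float] = None):
    """Time-averaged rate autocorrelation Cbar_phiphi(lag) from the grid.

    <phi phi>(t' + lag, t') is evaluated with the bivariate kernel and
    averaged over t' in the fixed window [transient, transient + t_span)
    for every lag (the grid must extend to transient + t_span + max_lag).
    For periodic drive ``t_span`` should be a whole number of drive
    periods.  Returns (lags, Cbar) for lags >= 0 (the function is even).
    """
    dt = gridsol.grid.dt
    n_lag = int(round(max_lag / dt))
    n0 = gridsol.n_transient
    n_t = len(gridsol.times)
    if t_span is None:
        n_win = n_t - n0 - n_lag
    else:
        n_win = int(round(t_span / dt))
    if n_win < 1 or n0 + n_win + n_lag > n_t:
        raise ValueError("grid span shorter than transient + t_span + max_lag")
    m, c = gridsol.m, gridsol.c
    cd = np.diag(c)
    j = np.arange(n0, n0 + n_win)
    g_lags = np.empty(n_lag + 1)
    for lag in range(n_lag + 1):
        i = j + lag
        vals = relu_cross_grid(m[i], m[j], cd[i], cd[j], c[i, j])
        g_lags[lag] = vals.mean()
    lags = np.arange(n_lag + 1) * dt
    return lags, g_lags


def mc_single_site_oracle(
    config: NetworkConfig,
    protocol: InputProtocol = InputProtocol(),
    grid: GridSpec = GridSpec(dt=0.05, transient=5.0, duration=10.0),
    M: int = 2000,
    iterations: int = 12,
    damping: float = 0.5,
    seed: int = 0,
):
    """Monte-Carlo single-site solution of the mean-field self-consistency.

    Iterates: sample M Gaussian noise paths with the current covariance
    q(t,s), integrate the single-site dynamics per path, re-estimate q from
    sample moments (fixed-point damping).  Independent check of the grid
    solver on coarse grids.

    Returns dict with times, m, c (empirical residual covariance), nu and
    the per-entry Monte-Carlo standard error scale of c.
    """
    tau = config.tau
    # the oracle tolerates coarse grids (it is a cross-check, not the solver)
    times = grid.times(tau, max_frac=0.25)
    n_t = len(times)
    if n_t > 401:
        raise ValueError("oracle restricted to coarse grids (<= 400 intervals)")
    if M < 100:
        raise ValueError("need at least 100 sample paths")
    dt = grid.dt
    delta = dt / tau
    g2 = config.g**2
    sN = np.sqrt(config.N)
    j0, i0 = config.j0_eff, config.i0_eff
    drive = _common_drive(protocol, times)
    rng = np.random.default_rng(seed)
    q = np.zeros((n_t, n_t))
    m = np.zeros(n_t)
    h = np.zeros((M, n_t))
    for it in range(iterations):
        if np.max(np.abs(q)) > 0:
            try:
                L = np.linalg.cholesky(q + 1e-10 * np.eye(n_t))
            except np.linalg.LinAlgError:
                warnings.warn("clipping negative eigenvalues of q", RuntimeWarning)
                w, V = np.linalg.eigh(q)
                q_fix = (V * np.maximum(w, 0.0)) @ V.T
                L = np.linalg.cholesky(q_fix + 1e-10 * np.eye(n_t))
            eta = rng.standard_normal((M, n_t)) @ L.T
        else:
            eta = np.zeros((M, n_t))
        h[:, 0] = 0.0
        m[0] = 0.0
        for n in range(n_t - 1):
            nu_n = np.maximum(m[n] + h[:, n], 0.0).mean()
            m[n + 1] = m[n] + delta * (-m[n] - sN * j0 * nu_n + sN * i0 + drive[n])
            h[:, n + 1] = (1.0 - delta) * h[:, n] + delta * eta[:, n]
        phi = np.maximum(m[None, :] + h, 0.0)
        q_new = g2 * (phi.T @ phi) / M
        q = (1.0 - damping) * q + damping * q_new
    c_emp = (h.T @ h) / M
    nu = np.maximum(m[None, :] + h, 0.0).mean(axis=0)
    # scale of MC error on c entries
    var_h = h.var(axis=0)
    se_scale = np.sqrt(np.outer(var_h, var_h) + c_emp**2) / np.sqrt(M)
    return {"times": times, "m": m, "c": c_emp, "nu": nu, "c_se": se_scale, "q": q}
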