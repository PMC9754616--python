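"""Critical input amplitude: bisection on the zero of lambda_1(I1) and
parameter sweeps (network size N, balance tightness K, gain g, input
frequency f).

``find_critical_amplitude`` accepts any callable I1 -> lambda_1.  The
callable may return a bare float (deterministic mean-field exponents) or a
(value, stderr) pair / LyapunovEstimate (noisy simulation estimates); in
the noisy case sign decisions use a two-standard-error guard with
re-evaluation at doubled measurement time on ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from balchaos.dmft import GridSpec, solve_mcr, solve_tangent
from balchaos.dmft_stationary import solve_independent_drive
from balchaos.lyapunov import LyapunovEstimate, le_tangent
from balchaos.network import InputProtocol, NetworkConfig, build_coupling

__all__ = [
    "NoCrossingError",
    "CriticalAmplitude",
    "find_critical_amplitude",
    "sweep",
    "dmft_lambda1_factory",
    "sim_lambda1_factory",
]


class NoCrossingError(RuntimeError):
    """No sign change of lambda_1 found within the expanded bracket."""


@dataclass
class CriticalAmplitude:
    value: float
    bracket: tuple
    n_evals: int


def _eval(fn, I1, level=0):
    out = fn(I1, level) if _takes_level(fn) else fn(I1)
    if isinstance(out, LyapunovEstimate):
        return out.lambda1, out.stderr
    if isinstance(out, tuple):
        return float(out[0]), float(out[1])
    return float(out), 0.0


def _takes_level(fn) -> bool:
    return getattr(fn, "accepts_level", False)


def _sign(fn, I1, max_level=2):
    """Sign of lambda_1(I1) with a 2-stderr guard on noisy estimates."""
    level = 0
    val, err = _eval(fn, I1, level)
    while err > 0 and abs(val) < 2.0 * err and level < max_level and _takes_level(fn):
        level += 1
        val, err = _eval(fn, I1, level)
    return np.sign(val), val, err


def find_critical_amplitude(
    lambda1_fn: Callable,
    bracket: tuple = (0.1, 10.0),
    rel_tol: float = 0.01,
    max_doublings: int = 20,
) -> CriticalAmplitude:
    """Bisect the zero crossing of lambda_1(I1) to relative precision.

    The bracket [a, b] must satisfy lambda_1(a) > 0 > lambda_1(b); if not,
    it is expanded geometrically (x2 per side, up to ``max_doublings``).
    """
    a, b = float(bracket[0]), float(bracket[1])
    if not 0 < a < b:
        raise ValueError("need 0 < a < b")
    n_evals = 0
    sa, va, _ = _sign(lambda1_fn, a)
    sb, vb, _ = _sign(lambda1_fn, b)
    n_evals += 2
    d = 0
    while sa <= 0 and d < max_doublings:
        b, sb = a, sa
        a /= 2.0
        sa, va, _ = _sign(lambda1_fn, a)
        n_evals += 1
        d += 1
    d = 0
    while sa > 0 and sb >= 0 and d < max_doublings:
        a, sa = b, sb
        b *= 2.0
        sb, vb, _ = _sign(lambda1_fn, b)
        n_evals += 1
        d += 1
    if not (sa > 0 > sb):
        raise NoCrossingError(
            f"no zero crossing: lambda1({a}) sign {sa}, lambda1({b}) sign {sb}"
        )
    while (b - a) / (0.5 * (a + b)) > rel_tol:
        mid = 0.5 * (a + b)
        sm, vm, _ = _sign(lambda1_fn, mid)
        n_evals += 1
        if sm > 0:
            a = mid
        elif sm < 0:
            b = mid
        else:  # exact zero
            return CriticalAmplitude(mid, (a, b), n_evals)
    return CriticalAmplitude(0.5 * (a + b), (a, b), n_evals)


def dmft_lambda1_factory(
    config: NetworkConfig,
    input_type: str,
    f: float,
    grid: Optional[GridSpec] = None,
    n_lags: int = 1024,
    span: float = 50.0,
):
    """lambda_1(I1) via mean-field theory.

    Common input: non-stationary two-time solver; independent input:
    stationary solver with phase quadrature.  For the independent case the
    fixed-point iteration is warm-started from the previous call's
    solution, which accelerates bisection considerably.
    """
    if input_type == "common":
        if grid is None:
            period = 1.0 / f if f > 0 else 10.0
            grid = GridSpec(dt=0.05 * config.tau, transient=20.0 * config.tau,
                            duration=max(5 * period, 25.0 * config.tau))

        def fn(I1):
            protocol = InputProtocol(kind="common_sin", I1=I1, f=f)
            sol = solve_mcr(config, protocol, grid)
            return solve_tangent(sol).lambda1

        return fn
    if input_type == "independent":
        state = {"c": None}

        def fn(I1):
            protocol = InputProtocol(kind="independent_sin", I1=I1, f=f)
            sol = solve_independent_drive(
                config, protocol, n_lags=n_lags, span=span, c_init=state["c"]
            )
            state["c"] = sol.c_resid
            return sol.lambda1

        return fn
    raise ValueError("input_type must be 'common' or 'independent'")


def sim_lambda1_factory(
    config: NetworkConfig,
    input_type: str,
    f: float,
    coupling_seed: int,
    input_seed: int = 0,
    T_measure: float = 150.0,
    dt: float = 0.02,
    T_transient: float = 30.0,
    T_tangent_transient: float = 20.0,
):
    """Noisy lambda_1(I1) from a tangent-space simulation on one coupling
    realisation; supports the doubled-T refinement protocol of the
    bisection (``level`` doubles the measurement window)."""
    J = build_coupling(config, coupling_seed)
    kind = "common_sin" if input_type == "common" else "independent_sin"

    def fn(I1, level=0):
        protocol = InputProtocol(kind=kind, I1=I1, f=f, seed=input_seed)
        return le_tangent(
            J, config, protocol,
            T_transient=T_transient,
            T_tangent_transient=T_tangent_transient,
            T_measure=T_measure * (2**level),
            dt=dt,
            seed=input_seed + 1,
        )

    fn.accepts_level = True
    return fn


def sweep(
    axis: str,
    values: Sequence,
    base_config: NetworkConfig,
    input_type: str,
    f: float,
    method: str = "dmft",
    seeds: Iterable[int] = (0,),
    bracket: Optional[tuple] = None,
    rel_tol: float = 0.01,
    **factory_kwargs,
) -> pd.DataFrame:
    """Critical amplitude along one parameter axis.

    axis in {"N", "K", "g", "f"}; ``method`` 'dmft' (one row per point) or
    'simulation' (one row per point and coupling seed; aggregate over
    seeds downstream).  Per-point failures are recorded (NaN) and the sweep
    continues.
    """
    if axis not in ("N", "K", "g", "f"):
        raise ValueError("axis must be one of N, K, g, f")
    rows = []
    for val in values:
        cfg = base_config
        ff = f
        if axis == "N":
            cfg = NetworkConfig(N=int(val), g=cfg.g, J0=cfg.J0, I0=cfg.I0,
                                tau=cfg.tau, K=cfg.K, transfer=cfg.transfer)
        elif axis == "K":
            cfg = NetworkConfig(N=cfg.N, g=cfg.g, J0=cfg.J0, I0=cfg.I0,
                                tau=cfg.tau, K=int(val), transfer=cfg.transfer)
        elif axis == "g":
            cfg = NetworkConfig(N=cfg.N, g=float(val), J0=cfg.J0, I0=cfg.I0,
                                tau=cfg.tau, K=cfg.K, transfer=cfg.transfer)
        else:
            ff = float(val)
        if bracket is None:
            if input_type == "common" and cfg.transfer == "relu" and cfg.i0_eff > 0:
                brk = (0.1, 2.0 * np.sqrt(cfg.N) * cfg.i0_eff)
            else:
                brk = (0.01, 10.0)
        else:
            brk = bracket
        seed_list = list(seeds) if method == "simulation" else [None]
        for sd in seed_list:
            try:
                if method == "dmft":
                    fn = dmft_lambda1_factory(cfg, input_type, ff, **factory_kwargs)
                else:
                    fn = sim_lambda1_factory(cfg, input_type, ff, coupling_seed=sd,
                                             **factory_kwargs)
                res = find_critical_amplitude(fn, brk, rel_tol=rel_tol)
                rows.append({"axis": axis, "axis_value": val, "I1crit": res.value,
                             "bracket_lo": res.bracket[0], "bracket_hi": res.bracket[1],
                             "method": method, "input_type": input_type,
                             "seed": sd, "error": ""})
            except Exception as exc:  # per-point failure: record and continue
                rows.append({"axis": axis, "axis_value": val, "I1crit": np.nan,
                             "bracket_lo": np.nan, "bracket_hi": np.nan,
                             "method": method, "input_type": input_type,
                             "seed": sd, "error": str(exc)})
    return pd.DataFrame(rows)
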