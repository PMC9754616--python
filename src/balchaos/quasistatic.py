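"""Quasi-static theory for slowly varying common input.

When the common drive varies much more slowly than the intrinsic network
fluctuations (tau f << 1), the exponent is the duration-weighted average of
the local exponents of *silent* episodes (total input negative, all rates
zero, lambda_local = -1/tau) and *chaotic* episodes (lambda_local =
lambda1_const(g), the autonomous exponent, input-amplitude independent by
positive homogeneity of the threshold-linear transfer):

    lambda_1 = -(1/tau) P_silent + lambda1_const(g) (1 - P_silent).

For sinusoidal drive of amplitude I1 the silent fraction of a period is
P_silent = arccos(sqrt(N) I0 / I1) / pi (zero when I1 <= sqrt(N) I0); for
an Ornstein-Uhlenbeck drive of intensity D and correlation time tau_s it is
the Gaussian tail P_silent = erfc(sqrt(N) I0 / sqrt(2 tau_s D)) / 2.
Setting lambda_1 = 0 gives closed forms for the critical amplitude and
intensity; both diverge when lambda1_const reaches 1/tau (arbitrarily
strong slow input can no longer suppress chaos).
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import erfc, erfcinv

from balchaos.dmft_stationary import lambda1_const

__all__ = [
    "qs_lambda1_sin",
    "qs_crit_sin",
    "qs_lambda1_ou",
    "qs_crit_ou",
    "attenuation",
    "lambda1_const_table",
]


def _lam_const(g: float, lam_const: Optional[float], tau: float) -> float:
    return lambda1_const(g, tau=tau) if lam_const is None else lam_const


def qs_lambda1_sin(
    g: float,
    I1: float,
    N: float,
    I0: float = 1.0,
    tau: float = 1.0,
    lam_const: Optional[float] = None,
) -> float:
    """Episode-averaged exponent for slow common sinusoidal drive.

    ``lam_const`` overrides the autonomous exponent (otherwise computed via
    stationary DMFT and cached).
    """
    if I1 < 0:
        raise ValueError("I1 must be nonnegative")
    lc = _lam_const(g, lam_const, tau)
    thr = np.sqrt(N) * I0
    if I1 <= thr:
        return lc
    p_silent = np.arccos(thr / I1) / np.pi
    return -p_silent / tau + lc * (1.0 - p_silent)


def qs_crit_sin(
    g: float,
    N: float,
    I0: float = 1.0,
    tau: float = 1.0,
    lam_const: Optional[float] = None,
) -> float:
    """Critical common amplitude sqrt(N) I0 sec(pi lam_c / (1/tau + lam_c)).

    Returns +inf when lam_const >= 1/tau (no slow common input suppresses
    chaos); reduces to sqrt(N) I0 as lam_const -> 0+.
    """
    lc = _lam_const(g, lam_const, tau)
    if lc >= 1.0 / tau:
        return np.inf
    if lc <= 0:
        return np.sqrt(N) * I0
    return np.sqrt(N) * I0 / np.cos(np.pi * lc / (1.0 / tau + lc))


def qs_lambda1_ou(
    g: float,
    D: float,
    tau_s: float,
    N: float,
    I0: float = 1.0,
    tau: float = 1.0,
    lam_const: Optional[float] = None,
) -> float:
    """Episode-averaged exponent for slow common OU drive of intensity D."""
    if D < 0 or tau_s <= 0:
        raise ValueError("need D >= 0 and tau_s > 0")
    lc = _lam_const(g, lam_const, tau)
    if D == 0:
        return lc
    arg = np.sqrt(N) * I0 / np.sqrt(2.0 * tau_s * D)
    p_silent = 0.5 * erfc(arg)
    return -p_silent / tau + lc * (1.0 - p_silent)


def qs_crit_ou(
    g: float,
    tau_s: float,
    N: float,
    I0: float = 1.0,
    tau: float = 1.0,
    lam_const: Optional[float] = None,
) -> float:
    """Critical OU intensity D_crit; +inf marker when lam_const >= 1/tau."""
    lc = _lam_const(g, lam_const, tau)
    if lc >= 1.0 / tau:
        return np.inf
    if lc <= 0:
        return 0.0
    x = erfcinv(2.0 * lc / (1.0 / tau + lc))
    return N * I0**2 / (2.0 * tau_s) / x**2


def attenuation(f: float, tau: float = 1.0) -> float:
    """Low-pass attenuation 1/sqrt(1 + (2 pi f tau)^2) of the leak term."""
    if f < 0:
        raise ValueError("f must be nonnegative")
    return 1.0 / np.sqrt(1.0 + (2.0 * np.pi * f * tau) ** 2)


def lambda1_const_table(
    g_min: float = 1.4,
    g_max: float = 2.4,
    n: int = 21,
    tau: float = 1.0,
) -> Callable[[float], float]:
    """Cubic interpolant of the autonomous exponent lambda1_const(g).

    Useful when the quasi-static formulas are evaluated on dense g grids:
    the stationary solver runs once per node instead of once per query.
    """
    gs = np.linspace(g_min, g_max, n)
    vals = np.array([lambda1_const(g, tau=tau) for g in gs])
    return CubicSpline(gs, vals)
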