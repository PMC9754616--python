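"""Target-based (full-FORCE) learning in balanced rate networks.

A randomly coupled *teacher* network is driven by sinusoidal input
dI_i = I1 sin(2 pi f t + theta_i) (equal phases: common; random phases:
independent) and its total incoming currents

    eta^T_i(t) = sum_j J^T_ij phi(h^T_j) + sqrt(N) I0 + dI_i(t)

are recorded.  A *student* network with the same architecture but no
time-varying drive is trained online by recursive least squares (RLS) so
that its recurrent currents match eta^T: all rows of J^S and the readout
weights w share a single inverse-correlation matrix over the regressor
phi(h^S), updated every Euler step.  After training the student should
autonomously generate z(t) = sum_i w_i phi(h^S_i) ~ sin(2 pi f t); the
normalised test error E_test over 50 output periods quantifies success.

Whether the drive suppresses chaos in the teacher (lambda_1 <= 0) is the
controlling factor for learnability, which is why common input - largely
cancelled by the balanced network's recurrent feedback - needs much larger
amplitude than independent input for the same test error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

from balchaos.lyapunov import LyapunovEstimate, le_tangent
from balchaos.network import (
    CouplingMatrix,
    InputProtocol,
    NetworkConfig,
    build_coupling,
    get_transfer,
    simulate,
)

__all__ = ["TeachRun", "TrainResult", "run_teacher", "train_student", "evaluate"]


@dataclass
class TeachRun:
    """Recorded teacher currents over a phase-locked training window."""

    config: NetworkConfig
    protocol: InputProtocol
    eta: np.ndarray  # (N, n_steps) target currents at Euler steps
    dt: float
    n_steps_per_period: int
    lambda1: Optional[LyapunovEstimate]
    coupling_seed: int

    @property
    def n_steps(self) -> int:
        return self.eta.shape[1]


@dataclass
class TrainResult:
    """Student couplings, readout, and training/testing diagnostics."""

    J_S: np.ndarray
    w: np.ndarray
    beta: float
    config: NetworkConfig
    f: float
    dt: float
    h_state: np.ndarray
    phase_step: int
    train_error: list = field(default_factory=list)
    test_error_trace: list = field(default_factory=list)
    E_test: Optional[float] = None
    passes_run: int = 0


def run_teacher(
    config: NetworkConfig,
    protocol: InputProtocol,
    n_periods: int = 10,
    dt: float = 0.01,
    T_transient: float = 50.0,
    seed: int = 0,
    compute_lambda1: bool = True,
    lyap_T_measure: float = 150.0,
) -> TeachRun:
    """Simulate the driven teacher and record its total incoming currents.

    Balanced initialisation (mean -J0/sqrt(N), variance g^2/N couplings);
    Euler integration at the learning step dt; the recording window is an
    integer number of drive periods starting at drive phase zero.
    """
    if protocol.f <= 0:
        raise ValueError("teacher drive needs f > 0")
    J = build_coupling(config, seed)
    phi, _ = get_transfer(config.transfer)
    steps_per_period = int(round(1.0 / (protocol.f * dt)))
    n_steps = n_periods * steps_per_period
    # transient rounded to whole periods so recording starts at phase 0
    n_trans_periods = int(np.ceil(T_transient * protocol.f))
    traj = simulate(
        J, config, protocol,
        T=n_trans_periods / protocol.f, dt=dt, seed=seed + 1, method="euler",
        store_stride=10**9,
    )
    h = traj.h_final
    N = config.N
    static = config.static_input()
    phases = protocol.frozen_phases(N)
    tau = config.tau
    eta = np.empty((N, n_steps))
    t0 = n_trans_periods / protocol.f
    for n in range(n_steps):
        t = t0 + n * dt
        dI = protocol.I1 * np.sin(2.0 * np.pi * protocol.f * t + phases)
        rec = J.weights @ phi(h)
        eta[:, n] = rec + static + dI
        h = h + (dt / tau) * (-h + rec + static + dI)
    lam = None
    if compute_lambda1:
        lam = le_tangent(
            J, config, protocol,
            T_transient=30.0, T_tangent_transient=20.0,
            T_measure=lyap_T_measure, dt=0.02, seed=seed + 2,
        )
    return TeachRun(config, protocol, eta, dt, steps_per_period, lam, seed)


def _autonomous_rollout(J_S, w, config, h, phase_step, f, dt, n_steps):
    """Euler rollout of the trained student; returns (z, h_end)."""
    phi, _ = get_transfer(config.transfer)
    static = config.static_input()
    tau = config.tau
    z = np.empty(n_steps)
    for n in range(n_steps):
        ph = phi(h)
        z[n] = w @ ph
        h = h + (dt / tau) * (-h + J_S @ ph + static)
    return z, h


def _e_test(z, phase_step, f, dt):
    t = (phase_step + np.arange(len(z))) * dt
    target = np.sin(2.0 * np.pi * f * t)
    denom = np.sum(target**2)
    return float(np.sum((z - target) ** 2) / denom)


def train_student(
    teach: Union[TeachRun, None],
    beta: float = 1.0,
    dt: Optional[float] = None,
    max_passes: int = 100,
    seed: int = 100,
    train_tol: float = 1e-2,
    test_periods_interleaved: int = 5,
    target_currents: Optional[Callable] = None,
    config: Optional[NetworkConfig] = None,
    f: Optional[float] = None,
    n_steps_window: Optional[int] = None,
) -> TrainResult:
    """Train the student couplings and readout by recursive least squares.

    One shared inverse-correlation matrix P (initialised to I/beta) over
    the regressor phi(h^S) drives rank-one updates of every row of J^S and
    of the readout w at every Euler step.  The teacher window is cycled;
    testing (autonomous rollout, ``test_periods_interleaved`` periods, state
    carried through so the network stays near the target trajectory) is
    interleaved after each pass.  Training stops when the running
    normalised training error falls below ``train_tol`` or after
    ``max_passes``.

    ``target_currents(step, phi_s)`` may replace the recorded teacher
    currents (used for fixtures with a known realisable solution); then
    ``config``, ``f`` and ``n_steps_window`` must be given.
    """
    if teach is not None:
        config = teach.config
        f = teach.protocol.f
        dt = teach.dt if dt is None else dt
        n_win = teach.n_steps
        eta = teach.eta
    else:
        if target_currents is None or config is None or f is None or n_steps_window is None:
            raise ValueError("need target_currents, config, f, n_steps_window")
        dt = 0.01 if dt is None else dt
        n_win = n_steps_window
        eta = None
    if beta <= 0:
        raise ValueError("beta must be positive")
    N = config.N
    phi, _ = get_transfer(config.transfer)
    static = config.static_input()
    tau = config.tau
    rng = np.random.default_rng(seed)
    J_S = build_coupling(config, seed).weights
    w = np.zeros(N)
    P = np.eye(N) / beta
    h = rng.standard_normal(N)
    steps_per_period = int(round(1.0 / (f * dt)))
    result = TrainResult(J_S, w, beta, config, f, dt, h, 0)
    phase = 0  # global step counter (drive phase = phase*dt)
    eta_scale = None
    if eta is not None:
        eta_scale = max(np.mean((eta - static[:, None]) ** 2), 1e-12)
    for p in range(max_passes):
        sq_err = 0.0
        for n in range(n_win):
            ph = phi(h)
            Pph = P @ ph
            denom = 1.0 + ph @ Pph
            k = Pph / denom
            tgt = eta[:, n] if eta is not None else target_currents(phase, ph)
            e = tgt - J_S @ ph - static
            J_S += np.outer(e, k)
            e_z = np.sin(2.0 * np.pi * f * phase * dt) - w @ ph
            w += e_z * k
            P -= np.outer(k, Pph)
            sq_err += np.mean(e**2)
            h = h + (dt / tau) * (-h + J_S @ ph + static)
            phase += 1
            if not np.isfinite(h).all():
                raise FloatingPointError(
                    "student dynamics diverged during training; "
                    "consider a larger regularisation beta"
                )
        if not np.isfinite(P).all():
            raise FloatingPointError(
                "RLS inverse-correlation matrix blew up; "
                "consider a larger regularisation beta"
            )
        result.train_error.append(
            sq_err / n_win / eta_scale if eta_scale else sq_err / n_win
        )
        result.passes_run = p + 1
        # interleaved test (whole periods, state carried through)
        n_test = test_periods_interleaved * steps_per_period
        z, h = _autonomous_rollout(J_S, w, config, h, phase, f, dt, n_test)
        et = _e_test(z, phase, f, dt)
        phase += n_test
        result.test_error_trace.append(et)
        if result.train_error[-1] < train_tol:
            break
    result.J_S = J_S
    result.w = w
    result.h_state = h
    result.phase_step = phase
    return result


def evaluate(result: TrainResult, f: Optional[float] = None, n_periods: int = 50) -> float:
    """Normalised test error of the autonomous student over ``n_periods``
    output periods, continuing from the (phase-aligned) training state."""
    f = result.f if f is None else f
    steps_per_period = int(round(1.0 / (f * result.dt)))
    n_steps = n_periods * steps_per_period
    z, h = _autonomous_rollout(
        result.J_S, result.w, result.config, result.h_state.copy(),
        result.phase_step, f, result.dt, n_steps,
    )
    e = _e_test(z, result.phase_step, f, result.dt)
    result.E_test = e
    return e
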