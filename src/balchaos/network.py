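"""Balanced firing-rate network construction and integration.

The model is a network of N rate units with synaptic currents h_i obeying

    tau dh_i/dt = -h_i + sum_j J_ij phi(h_j) + sqrt(N) I0 + dI_i(t),

with i.i.d. Gaussian couplings J_ij ~ N(-J0/sqrt(N), g^2/N).  The strongly
negative mean coupling dynamically cancels the large static drive
sqrt(N) I0 (the balanced state), pinning the population rate near I0/J0.
The time-dependent drive dI_i(t) is either *common* (identical across
neurons) or *independent* (random phase / independent realisation per
neuron); sinusoidal and Ornstein-Uhlenbeck protocols are provided.

Two structural variants are supported besides the dense single population:
a sparse two-population excitatory-inhibitory network (fixed in-degree K
per presynaptic block) and the classical zero-mean-coupling tanh network
used as a non-balanced control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Optional

import numpy as np
from scipy import sparse as sp

__all__ = [
    "NetworkConfig",
    "EIConfig",
    "InputProtocol",
    "CouplingMatrix",
    "Trajectory",
    "DivergenceError",
    "build_coupling",
    "build_ei_coupling",
    "make_input",
    "simulate",
    "input_decomposition",
    "phi_autocorr_time_avg",
]

TransferName = Literal["relu", "tanh", "linear"]


class DivergenceError(RuntimeError):
    """Raised when the integrated currents exceed the divergence bound."""

    def __init__(self, step: int, t: float, max_h: float):
        super().__init__(
            f"dynamics diverged at step {step} (t = {t:.3f}): max|h| = {max_h:.3e}"
        )
        self.step = step
        self.t = t


def get_transfer(name: TransferName) -> tuple[Callable, Callable]:
    """Return (phi, phi') for a named transfer function.

    phi'(0) = 0 for the threshold-linear case (subgradient convention).
    """
    if name == "relu":
        return (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float))
    if name == "tanh":
        return (np.tanh, lambda x: 1.0 / np.cosh(x) ** 2)
    if name == "linear":
        return (lambda x: x, lambda x: np.ones_like(x))
    raise ValueError(f"unknown transfer {name!r}")


@dataclass(frozen=True)
class NetworkConfig:
    """Single-population network parameters.

    If ``K`` is set, the effective coupling/input scales are J0*sqrt(K/N)
    and I0*sqrt(K/N) ('tightness of balance' convention), which removes the
    explicit N-dependence of the mean-field equations.
    """

    N: int
    g: float
    J0: float = 1.0
    I0: float = 1.0
    tau: float = 1.0
    K: Optional[int] = None
    transfer: TransferName = "relu"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.g < 0 or self.J0 < 0:
            raise ValueError("g and J0 must be nonnegative")
        if self.K is not None and not 0 < self.K:
            raise ValueError("K must be positive when set")

    @property
    def j0_eff(self) -> float:
        return self.J0 * np.sqrt(self.K / self.N) if self.K else self.J0

    @property
    def i0_eff(self) -> float:
        return self.I0 * np.sqrt(self.K / self.N) if self.K else self.I0

    def static_input(self) -> np.ndarray:
        return np.full(self.N, np.sqrt(self.N) * self.i0_eff)

    def mod_gain(self) -> np.ndarray:
        return np.ones(self.N)


@dataclass(frozen=True)
class EIConfig:
    """Sparse two-population excitatory-inhibitory network.

    Each neuron receives exactly K connections from each presynaptic
    population.  Couplings scale as 1/sqrt(K) and static drives as sqrt(K)
    (balanced-state convention); the excitatory efficacy ``alpha``
    multiplies all excitatory couplings and the excitatory static drive.
    Input modulation amplitudes are g*alpha*I1 (onto E) and 0.44*g*I1
    (onto I).
    """

    N_E: int
    N_I: int
    K: int
    g: float
    alpha: float
    tau: float = 1.0
    transfer: TransferName = "relu"

    def __post_init__(self) -> None:
        if self.K > min(self.N_E, self.N_I):
            raise ValueError("K must not exceed either population size")
        if self.K < 1:
            raise ValueError("K must be positive")

    @property
    def N(self) -> int:
        return self.N_E + self.N_I

    @property
    def block_weights(self) -> dict:
        sK = np.sqrt(self.K)
        return {
            "EE": self.g * self.alpha / sK,
            "EI": -1.11 * self.g / sK,
            "IE": self.g * self.alpha / sK,
            "II": -self.g / sK,
        }

    def static_input(self) -> np.ndarray:
        sK = np.sqrt(self.K)
        w_e = self.g * self.alpha * sK
        w_i = 0.44 * self.g * sK
        return np.concatenate([np.full(self.N_E, w_e), np.full(self.N_I, w_i)])

    def mod_gain(self) -> np.ndarray:
        return np.concatenate(
            [np.full(self.N_E, self.g * self.alpha), np.full(self.N_I, 0.44 * self.g)]
        )


InputKind = Literal["none", "common_sin", "independent_sin", "common_ou", "independent_ou"]


@dataclass(frozen=True)
class InputProtocol:
    """Time-dependent external drive dI_i(t).

    Sinusoidal kinds: dI_i = I1 sin(2 pi f t + theta_i), with theta_i = 0
    for common input and i.i.d. uniform phases for independent input.
    OU kinds: d(dI)/dt = -dI/tau_s + sqrt(2 D) xi(t); stationary variance
    D*tau_s; one shared realisation (common) or one per neuron
    (independent).
    """

    kind: InputKind = "none"
    I1: float = 0.0
    f: float = 0.0
    tau_s: float = 1.0
    D: float = 0.0
    seed: int = 0
    phases: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.I1 < 0:
            raise ValueError("I1 must be nonnegative")
        if self.kind in ("common_ou", "independent_ou") and self.tau_s <= 0:
            raise ValueError("OU correlation time tau_s must be positive")

    def frozen_phases(self, N: int) -> np.ndarray:
        """Per-neuron phases; drawn once per (seed, N) for independent input."""
        if self.kind == "common_sin":
            return np.zeros(N)
        if self.kind == "independent_sin":
            if self.phases is not None:
                if len(self.phases) != N:
                    raise ValueError("phases length must equal N")
                return np.asarray(self.phases, dtype=float)
            rng = np.random.default_rng(self.seed)
            return rng.uniform(0.0, 2.0 * np.pi, N)
        raise ValueError(f"no phases for kind {self.kind!r}")

    @property
    def period(self) -> float:
        return 1.0 / self.f if self.f > 0 else np.inf


class _InputStream:
    """Sequential access to dI_i at uniform step times t_n = n*dt (plus t0)."""

    def __init__(self, protocol: InputProtocol, N: int, dt: float, t0: float = 0.0):
        self.protocol = protocol
        self.N = N
        self.dt = dt
        self.t0 = t0
        kind = protocol.kind
        self._ou = kind in ("common_ou", "independent_ou")
        if kind in ("common_sin", "independent_sin"):
            self._phases = protocol.frozen_phases(N)
        elif self._ou:
            rng = np.random.default_rng(protocol.seed)
            self._rng = rng
            m = 1 if kind == "common_ou" else N
            self._m = m
            sigma = np.sqrt(protocol.D * protocol.tau_s)
            self._sigma = sigma
            self._decay = np.exp(-dt / protocol.tau_s)
            self._kick = sigma * np.sqrt(max(1.0 - self._decay**2, 0.0))
            # start from stationarity
            self._state = sigma * rng.standard_normal(m)
            self._step = 0

    def value(self, n: int) -> np.ndarray:
        """dI vector at step n.  OU kinds must be accessed with n monotone
        (n or any later step); deterministic kinds accept any n."""
        p = self.protocol
        t = self.t0 + n * self.dt
        if p.kind == "none" or p.I1 == 0 and not self._ou:
            return np.zeros(self.N)
        if p.kind in ("common_sin", "independent_sin"):
            return p.I1 * np.sin(2.0 * np.pi * p.f * t + self._phases)
        # OU
        while self._step < n:
            self._state = self._decay * self._state + self._kick * self._rng.standard_normal(self._m)
            self._step += 1
        if self._step != n:
            raise ValueError("OU input stream accessed non-monotonically")
        if self._m == 1:
            return np.full(self.N, self._state[0])
        return self._state.copy()


def make_input(protocol: InputProtocol, config, times) -> np.ndarray:
    """Materialise the per-neuron input series dI_i(t) on the given times.

    Times must be increasing and (for OU kinds) uniformly spaced; OU
    realisations use the exact exponential update and start from the
    stationary distribution.
    """
    times = np.asarray(times, dtype=float)
    N = config.N
    if protocol.kind == "none":
        return np.zeros((N, len(times)))
    if protocol.kind in ("common_sin", "independent_sin"):
        phases = protocol.frozen_phases(N)
        return protocol.I1 * np.sin(
            2.0 * np.pi * protocol.f * times[None, :] + phases[:, None]
        )
    dts = np.diff(times)
    if len(dts) and not np.allclose(dts, dts[0], rtol=1e-8):
        raise ValueError("OU input requires uniformly spaced times")
    dt = dts[0] if len(dts) else 1.0
    stream = _InputStream(protocol, N, dt, t0=times[0])
    out = np.empty((N, len(times)))
    for n in range(len(times)):
        out[:, n] = stream.value(n)
    return out


@dataclass
class CouplingMatrix:
    """Coupling weights plus provenance metadata."""

    weights: object  # dense ndarray or scipy CSR
    kind: Literal["dense", "ei"]
    seed: Optional[int]
    config: object

    @property
    def N(self) -> int:
        return self.weights.shape[0]

    def matvec(self, x: np.ndarray) -> np.ndarray:
        return self.weights @ x


def build_coupling(config: NetworkConfig, seed: int) -> CouplingMatrix:
    """Dense i.i.d. Gaussian couplings, mean -J0_eff/sqrt(N), variance g^2/N.

    Self-couplings are drawn like any other entry.  Bit-reproducible per
    seed.
    """
    rng = np.random.default_rng(seed)
    N = config.N
    mean = -config.j0_eff / np.sqrt(N)
    std = config.g / np.sqrt(N)
    W = rng.normal(mean, std, size=(N, N)) if std > 0 else np.full((N, N), mean)
    return CouplingMatrix(W, "dense", seed, config)


def build_ei_coupling(ei: EIConfig, seed: int) -> CouplingMatrix:
    """Block-sparse E-I couplings: exactly K inputs per presynaptic block.

    Row i has K nonzeros with the block-constant weight in the E column
    range and K in the I column range, positions uniform without
    replacement.
    """
    rng = np.random.default_rng(seed)
    N, N_E, N_I, K = ei.N, ei.N_E, ei.N_I, ei.K
    w = ei.block_weights
    indptr = np.arange(N + 1, dtype=np.int64) * (2 * K)
    indices = np.empty(N * 2 * K, dtype=np.int32)
    data = np.empty(N * 2 * K, dtype=np.float64)
    for i in range(N):
        pre_e = rng.choice(N_E, size=K, replace=False)
        pre_i = N_E + rng.choice(N_I, size=K, replace=False)
        lo = i * 2 * K
        indices[lo : lo + K] = np.sort(pre_e)
        indices[lo + K : lo + 2 * K] = np.sort(pre_i)
        if i < N_E:
            data[lo : lo + K] = w["EE"]
            data[lo + K : lo + 2 * K] = w["EI"]
        else:
            data[lo : lo + K] = w["IE"]
            data[lo + K : lo + 2 * K] = w["II"]
    W = sp.csr_matrix((data, indices, indptr), shape=(N, N))
    return CouplingMatrix(W, "ei", seed, ei)


@dataclass
class Trajectory:
    """Stored currents h_i(t) at a fixed stride, with derived rates."""

    times: np.ndarray  # (T,)
    h: np.ndarray  # (N, T)
    dt: float  # integration step
    stride: int
    config: object
    protocol: InputProtocol
    h_final: np.ndarray = field(repr=False, default=None)

    @property
    def dt_store(self) -> float:
        return self.dt * self.stride

    def rates(self) -> np.ndarray:
        phi, _ = get_transfer(self.config.transfer)
        return phi(self.h)

    def nu(self) -> np.ndarray:
        """Population mean firing rate nu(t) = (1/N) sum_i phi(h_i(t))."""
        return self.rates().mean(axis=0)


_DIVERGENCE_FACTOR = 1e6


def _rhs_factory(J: CouplingMatrix, config):
    phi, _ = get_transfer(config.transfer)
    static = config.static_input()
    gain = config.mod_gain()
    tau = config.tau
    W = J.weights

    def rhs(h, dI):
        return (-h + W @ phi(h) + static + gain * dI) / tau

    return rhs


def simulate(
    J: CouplingMatrix,
    config,
    protocol: InputProtocol = InputProtocol(),
    T: float = 100.0,
    dt: float = 0.01,
    h0: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
    store_stride: Optional[int] = None,
    method: Literal["heun", "euler"] = "heun",
) -> Trajectory:
    """Integrate the network for duration T.

    Heun (2nd order) by default; Euler selectable.  ``seed`` controls the
    initial condition draw (and is combined with the protocol seed for OU
    noise via the protocol itself).  Currents are stored every
    ``store_stride`` steps (default: every 0.1 tau).

    Raises :class:`DivergenceError` if any |h| exceeds 1e6*sqrt(N).
    """
    if dt > 0.05 * config.tau:
        raise ValueError("dt must satisfy dt <= 0.05*tau")
    N = config.N
    rng = np.random.default_rng(seed)
    h = np.array(h0, dtype=float) if h0 is not None else rng.standard_normal(N)
    if h.shape != (N,):
        raise ValueError("h0 must have shape (N,)")
    n_steps = int(round(T / dt))
    if store_stride is None:
        store_stride = max(1, int(round(0.1 * config.tau / dt)))
    stream = _InputStream(protocol, N, dt)
    rhs = _rhs_factory(J, config)
    n_stored = n_steps // store_stride + 1
    out = np.empty((N, n_stored))
    out_times = np.empty(n_stored)
    out[:, 0] = h
    out_times[0] = 0.0
    stored = 1
    bound = _DIVERGENCE_FACTOR * np.sqrt(N)
    dI_n = stream.value(0)
    for n in range(n_steps):
        f1 = rhs(h, dI_n)
        dI_next = stream.value(n + 1)
        if method == "heun":
            hp = h + dt * f1
            f2 = rhs(hp, dI_next)
            h = h + 0.5 * dt * (f1 + f2)
        else:
            h = h + dt * f1
        dI_n = dI_next
        if (n + 1) % store_stride == 0:
            out[:, stored] = h
            out_times[stored] = (n + 1) * dt
            stored += 1
        if (n + 1) % 50 == 0 or n == n_steps - 1:
            mx = np.max(np.abs(h))
            if not np.isfinite(mx) or mx > bound:
                raise DivergenceError(n + 1, (n + 1) * dt, mx)
    return Trajectory(
        out_times[:stored], out[:, :stored], dt, store_stride, config, protocol, h_final=h
    )


def input_decomposition(traj: Trajectory, J: CouplingMatrix, protocol: Optional[InputProtocol] = None):
    """Split the drive at the stored samples into external and recurrent parts.

    Returns a dict with per-neuron external input (static + dI), recurrent
    input sum_j J_ij phi(h_j), their population means, and the residual
    tau*dh/dt + h - (rec + ext) computed with central differences (zero up
    to O(dt_store^2) discretisation error).
    """
    protocol = protocol or traj.protocol
    config = traj.config
    phi, _ = get_transfer(config.transfer)
    rec = J.weights @ phi(traj.h)
    dI = make_input(protocol, config, traj.times)
    ext = config.static_input()[:, None] + config.mod_gain()[:, None] * dI
    dt_s = traj.dt_store
    dh = np.empty_like(traj.h)
    dh[:, 1:-1] = (traj.h[:, 2:] - traj.h[:, :-2]) / (2 * dt_s)
    dh[:, 0] = (traj.h[:, 1] - traj.h[:, 0]) / dt_s
    dh[:, -1] = (traj.h[:, -1] - traj.h[:, -2]) / dt_s
    residual = config.tau * dh + traj.h - rec - ext
    return {
        "external": ext,
        "recurrent": rec,
        "external_mean": ext.mean(axis=0),
        "recurrent_mean": rec.mean(axis=0),
        "residual": residual,
    }


def phi_autocorr_time_avg(
    traj: Trajectory,
    max_lag: float,
    t_start: float = 0.0,
    t_span: Optional[float] = None,
):
    """Time- and population-averaged rate autocorrelation Cbar(lag).

    Cbar(lag) = < phi_i(t'+lag) phi_i(t') >_{i, t'} with t' running over the
    fixed window [t_start, t_start + t_span) for every lag (the trajectory
    must extend to t_start + t_span + max_lag).  For periodic drive the
    window should be a whole number of drive periods, otherwise the
    cyclostationary modulation biases the average.  Returns (lags, Cbar)
    for lags >= 0 on the storage grid; the function is even in the lag.
    """
    dt_s = traj.dt_store
    n_lag = int(round(max_lag / dt_s))
    i0 = int(np.searchsorted(traj.times, t_start - 1e-12))
    n_avail = traj.h.shape[1] - i0
    if t_span is None:
        n_win = n_avail - n_lag
    else:
        n_win = int(round(t_span / dt_s))
    if n_win < 1 or n_win + n_lag > n_avail:
        raise ValueError("analysis window shorter than t_span + max_lag")
    R = traj.rates()[:, i0:]
    base = R[:, :n_win]
    cbar = np.empty(n_lag + 1)
    for lag in range(n_lag + 1):
        cbar[lag] = np.mean(base * R[:, lag : lag + n_win])
    lags = np.arange(n_lag + 1) * dt_s
    return lags, cbar
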