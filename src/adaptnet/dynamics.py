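"""The adaptive recurrent rate-network model.

A network of N rate neurons with dendritic potentials x, multi-timescale
spike-frequency adaptation (SFA) states a, and short-term synaptic
depression (STD) vesicle fractions b:

    tau_d * dx_i/dt = -x_i + u_i + sum_j w_ij b_j r_j
    r_i  = phi(x_i - a0_i - c * sum_k a_ik)
    tau_k * da_ik/dt = -a_ik + r_i
    db_i/dt = (1 - b_i)/tau_rec - b_i r_i / tau_rel

phi is a hard sigmoid with rounded (quadratic, C^1) corners and range [0, 1];
its nonnegative output enforces Dale's law on synaptic drive.  SFA acts as a
subtractive negative-feedback current; STD scales each presynaptic column of
W multiplicatively by the available fraction b in [0, 1].  With both
mechanisms disabled the model reduces to a leaky Hopfield-style rate network.

By default only excitatory neurons adapt; inhibitory neurons keep a = 0 and
b = 1 frozen.  Integration is fixed-step RK4 so that Lyapunov bookkeeping
aligns exactly with integration steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple, Union

import numpy as np

from . import _kernels
from .connectivity import WeightMatrix
from .exceptions import DivergenceError, ParameterError
from .stimuli import StimulusSpec

__all__ = [
    "ModelParams",
    "NetworkState",
    "Trajectory",
    "phi",
    "phi_prime",
    "rhs",
    "simulate",
    "relax_to_fixed_point",
]


@dataclass(frozen=True)
class ModelParams:
    """All scalar parameters of the model, plus per-mechanism switches.

    Attributes
    ----------
    tau_d : float
        Dendritic time constant (s).
    tau_k : tuple of float
        SFA time constants (s), strictly increasing.  The default three
        log-spaced values span fast to slow adaptation (0.3 s to 30 s).
    c : float
        SFA coupling gain (>= 0); total adaptation current is c * sum_k a_ik.
    a0 : float or array
        Constant shift inside the activation argument, setting the baseline
        operating point near the lower inflection of phi.  The default 0.05
        rests neurons slightly below the corner (low basal rate, reduced
        resting gain), so quiescence is stable and stimuli can recruit the
        network into its high-gain region.
    tau_rec, tau_rel : float
        STD vesicle recovery and release time constants (s).  The default
        ratio tau_rec/tau_rel = 22.5 gives strong depression: sustained
        firing at rate r depletes the steady-state available fraction to
        1/(1 + r*tau_rec/tau_rel).
    w_corner : float
        Corner half-width of the hard sigmoid, in (0, 0.5].
    sfa_enabled, std_enabled : bool
        Mechanism switches; a disabled mechanism is frozen at a = 0 / b = 1.
    adapting_population : str
        Which population tag carries adaptation: "E", "I", "all" or "none".
    """

    tau_d: float = 0.1
    tau_k: Tuple[float, ...] = (0.3, 3.0, 30.0)
    c: float = 0.5
    a0: Union[float, np.ndarray] = 0.05
    tau_rec: float = 2.25
    tau_rel: float = 0.1
    w_corner: float = 0.1
    sfa_enabled: bool = True
    std_enabled: bool = True
    adapting_population: str = "E"

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau_k", tuple(float(t) for t in self.tau_k))
        if self.tau_d <= 0 or self.tau_rec <= 0 or self.tau_rel <= 0:
            raise ParameterError("all time constants must be > 0")
        if len(self.tau_k) < 1 or any(t <= 0 for t in self.tau_k):
            raise ParameterError("need K >= 1 positive SFA time constants")
        if any(b <= a for a, b in zip(self.tau_k, self.tau_k[1:])):
            raise ParameterError("tau_k must be strictly increasing")
        if self.c < 0:
            raise ParameterError("c must be >= 0")
        if not 0.0 < self.w_corner <= 0.5:
            raise ParameterError("w_corner must be in (0, 0.5]")
        if self.adapting_population not in ("E", "I", "all", "none"):
            raise ParameterError(
                "adapting_population must be 'E', 'I', 'all' or 'none'"
            )

    @property
    def K(self) -> int:
        return len(self.tau_k)

    def with_condition(self, sfa: bool, std: bool) -> "ModelParams":
        return replace(self, sfa_enabled=sfa, std_enabled=std)

    def a0_vector(self, N: int) -> np.ndarray:
        a0 = np.asarray(self.a0, dtype=float)
        return np.full(N, float(a0)) if a0.ndim == 0 else a0.copy()

    def adapt_mask(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels, dtype="<U1")
        if self.adapting_population == "all":
            return np.ones(labels.size, dtype=bool)
        if self.adapting_population == "none":
            return np.zeros(labels.size, dtype=bool)
        return labels == self.adapting_population

    def tau_k_array(self) -> np.ndarray:
        return np.asarray(self.tau_k, dtype=float)


@dataclass
class NetworkState:
    """One instant of the network: x (N,), a (N, K), b (N,)."""

    x: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        N = self.x.size
        if self.a.ndim != 2 or self.a.shape[0] != N:
            raise ParameterError("a must have shape (N, K)")
        if self.b.shape != (N,):
            raise ParameterError("b must have shape (N,)")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def K(self) -> int:
        return self.a.shape[1]

    @classmethod
    def initial(
        cls,
        N: int,
        K: int,
        seed: Optional[int] = 0,
        x0_scale: float = 0.01,
    ) -> "NetworkState":
        """The standard start: x ~ Normal(0, x0_scale^2), a = 0, b = 1."""
        if seed is None:
            x = np.zeros(N)
        else:
            x = np.random.default_rng(seed).normal(0.0, x0_scale, size=N)
        return cls(x, np.zeros((N, K)), np.ones(N))

    def pack(self) -> np.ndarray:
        """Flatten to [x, a (timescale-major), b]."""
        return np.concatenate([self.x, self.a.ravel(order="F"), self.b])

    @classmethod
    def unpack(cls, y: np.ndarray, N: int, K: int) -> "NetworkState":
        x = y[:N].copy()
        a = y[N : N + N * K].reshape((N, K), order="F").copy()
        b = y[N + N * K :].copy()
        return cls(x, a, b)


@dataclass
class Trajectory:
    """A sampled run: arrays indexed (sample, neuron[, timescale])."""

    times: np.ndarray
    x: np.ndarray
    a: np.ndarray
    b: np.ndarray
    rates: np.ndarray
    stimulus: np.ndarray

    def state_at(self, i: int) -> NetworkState:
        return NetworkState(self.x[i], self.a[i], self.b[i])

    @property
    def n_samples(self) -> int:
        return self.times.size


def phi(h, w_corner: float = 0.1):
    """Hard sigmoid with quadratic corners: 0 below -w, identity on
    [w, 1-w], 1 above 1+w, C^1 everywhere.  Vectorizes elementwise."""
    h_arr = np.asarray(h, dtype=float)
    w = float(w_corner)
    out = np.where(
        h_arr <= -w,
        0.0,
        np.where(
            h_arr <= w,
            (h_arr + w) ** 2 / (4.0 * w),
            np.where(
                h_arr <= 1.0 - w,
                h_arr,
                np.where(
                    h_arr <= 1.0 + w,
                    1.0 - (1.0 - h_arr + w) ** 2 / (4.0 * w),
                    1.0,
                ),
            ),
        ),
    )
    return float(out) if np.isscalar(h) else out


def phi_prime(h, w_corner: float = 0.1):
    """Exact derivative of :func:`phi` (piecewise linear, range [0, 1])."""
    h_arr = np.asarray(h, dtype=float)
    w = float(w_corner)
    out = np.where(
        h_arr <= -w,
        0.0,
        np.where(
            h_arr <= w,
            np.clip((h_arr + w) / (2.0 * w), 0.0, 1.0),
            np.where(
                h_arr <= 1.0 - w,
                1.0,
                np.where(
                    h_arr <= 1.0 + w,
                    np.clip((1.0 - h_arr + w) / (2.0 * w), 0.0, 1.0),
                    0.0,
                ),
            ),
        ),
    )
    return float(out) if np.isscalar(h) else out


def activation_input(state: NetworkState, p: ModelParams) -> np.ndarray:
    """The activation argument h = x - a0 - c * sum_k a_ik (SFA term only
    where the mechanism is enabled; a is zero for non-adapting neurons)."""
    h = state.x - p.a0_vector(state.n)
    if p.sfa_enabled:
        h = h - p.c * state.a.sum(axis=1)
    return h


def _kernel_args(W: WeightMatrix, p: ModelParams):
    adapt = p.adapt_mask(W.labels)
    return (
        np.ascontiguousarray(W.values),
        adapt,
        p.sfa_enabled,
        p.std_enabled,
        p.a0_vector(W.n),
        p.c,
        p.tau_d,
        p.tau_k_array(),
        p.tau_rec,
        p.tau_rel,
        p.w_corner,
    )


def rhs(
    state: NetworkState,
    u: np.ndarray,
    W: WeightMatrix,
    p: ModelParams,
) -> NetworkState:
    """Time derivative (dx/dt, da/dt, db/dt) of the model at one state.

    Disabled mechanisms and non-adapting neurons contribute zero derivative
    rows; with STD disabled the recurrent drive uses b = 1 regardless of the
    stored b.
    """
    N, K = state.n, state.K
    if W.n != N:
        raise ParameterError(f"W is {W.n}x{W.n} but state has N = {N}")
    if K != p.K:
        raise ParameterError(f"state has K = {K} but params have K = {p.K}")
    u = np.asarray(u, dtype=float)
    if u.shape != (N,):
        raise ParameterError(f"u must have shape ({N},), got {u.shape}")
    y = state.pack()
    if not np.all(np.isfinite(y)):
        raise ParameterError("non-finite state")
    dy = np.empty_like(y)
    _kernels.rhs_flat(
        y, u, *_kernel_args(W, p), dy, np.empty(N), np.empty(N)
    )
    return NetworkState.unpack(dy, N, K)


def _check_dt(dt: float, p: ModelParams) -> None:
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    guard = min(p.tau_d, p.tau_rel) / 5.0
    if dt > guard + 1e-15:
        raise ParameterError(
            f"dt = {dt:g} exceeds the stability guard min(tau_d, tau_rel)/5 "
            f"= {guard:g}"
        )


def _rates_along(Y: np.ndarray, N: int, K: int, p: ModelParams) -> np.ndarray:
    x = Y[:, :N]
    a_sum = Y[:, N : N + N * K].reshape(Y.shape[0], K, N).sum(axis=1)
    a0 = p.a0_vector(N)[None, :]
    h = x - a0 - (p.c * a_sum if p.sfa_enabled else 0.0)
    return phi(h, p.w_corner)


def simulate(
    W: WeightMatrix,
    p: ModelParams,
    stim: StimulusSpec,
    T: float,
    dt: float = 0.01,
    seed: Optional[int] = 0,
    x0: Optional[NetworkState] = None,
    x0_scale: float = 0.01,
    sample_every: int = 10,
) -> Trajectory:
    """Fixed-step RK4 integration over [0, T], sampled every ``sample_every``
    steps.

    The initial condition is x ~ Normal(0, x0_scale^2) (seeded), a = 0,
    b = 1, unless an explicit ``x0`` state is given.  Deterministic given
    (W, p, stim, seed).

    Raises
    ------
    DivergenceError
        If |x|_inf exceeds 1e6, reporting the time of blow-up.
    """
    if T <= 0:
        raise ParameterError(f"T must be > 0, got {T}")
    _check_dt(dt, p)
    N, K = W.n, p.K
    if stim.n != N:
        raise ParameterError("stimulus dimension does not match network size")
    state0 = x0 if x0 is not None else NetworkState.initial(N, K, seed, x0_scale)
    n_steps = int(round(T / dt))
    Y, status, blow_step = _kernels.simulate_loop(
        state0.pack(),
        n_steps,
        sample_every,
        dt,
        stim.amplitudes,
        stim.t_on,
        stim.t_off,
        *_kernel_args(W, p),
    )
    if status == _kernels.DIVERGED:
        raise DivergenceError(blow_step * dt)
    times = np.arange(Y.shape[0]) * (sample_every * dt)
    rates = _rates_along(Y, N, K, p)
    return Trajectory(
        times=times,
        x=Y[:, :N].copy(),
        a=np.ascontiguousarray(
            Y[:, N : N + N * K].reshape(Y.shape[0], K, N).transpose(0, 2, 1)
        ),
        b=Y[:, N + N * K :].copy(),
        rates=rates,
        stimulus=stim.u_array(times),
    )


@dataclass
class FixedPointResult:
    state: NetworkState
    converged: bool
    t_elapsed: float
    residual_norm: float


def relax_to_fixed_point(
    W: WeightMatrix,
    p: ModelParams,
    u: np.ndarray,
    tol: float = 1e-10,
    T_max: float = 1000.0,
    dt: float = 0.01,
    x0: Optional[NetworkState] = None,
) -> FixedPointResult:
    """Integrate under constant input from the zero-noise start until the
    derivative norm falls below ``tol`` (or ``T_max`` is reached).

    Non-convergence is a reported outcome (``converged=False``), not an
    exception — chaotic configurations simply never settle.
    """
    _check_dt(dt, p)
    N, K = W.n, p.K
    u = np.asarray(u, dtype=float)
    if u.shape != (N,):
        raise ParameterError(f"u must have shape ({N},)")
    state0 = x0 if x0 is not None else NetworkState.initial(N, K, seed=None)
    max_steps = int(round(T_max / dt))
    y, steps, converged, status = _kernels.relax_loop(
        state0.pack(),
        max_steps,
        10,
        tol,
        dt,
        u,
        *_kernel_args(W, p),
    )
    state = NetworkState.unpack(y, N, K)
    if status == _kernels.DIVERGED:
        return FixedPointResult(state, False, steps * dt, np.inf)
    resid = rhs(state, u, W, p)
    rnorm = float(
        max(
            np.max(np.abs(resid.x)),
            np.max(np.abs(resid.a)) if resid.a.size else 0.0,
            np.max(np.abs(resid.b)),
        )
    )
    return FixedPointResult(state, bool(converged), steps * dt, rnorm)
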