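"""Random structural synaptic weight matrices.

Generators for the standard ensembles of network stability theory: dense and
sparse i.i.d. Gaussian matrices, Dale's-law matrices with separate excitatory
and inhibitory weight distributions, per-row excitation/inhibition balancing,
low-rank perturbations, and diagonal negative feedback.

Conventions: ``values[i, j]`` is the weight from presynaptic neuron ``j`` onto
postsynaptic neuron ``i``; columns therefore share the sign statistics of
their presynaptic population under Dale's law.  The diagonal is generated like
any other entry — the leak term of the dynamics is kept separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import BalancingInfeasibleError, ParameterError

__all__ = [
    "NetworkSpec",
    "WeightMatrix",
    "generate_iid",
    "generate_dale",
    "balance_rows",
    "add_low_rank",
    "diagonal_feedback",
]

#: Default stability-experiment ensemble: bulk radius sigma*sqrt(N*d) = 3.0
#: at N=300, d=1/3 (the linearized no-adaptation network has many unstable
#: eigenmodes), mean excitatory weight 0.6*sigma, inhibitory magnitude (4/3)
#: of that (modest inhibitory dominance).
DEFAULT_SIGMA = 0.3
DEFAULT_MU_E = 0.6 * DEFAULT_SIGMA
DEFAULT_MU_I_MAG = 4.0 / 3.0 * DEFAULT_MU_E


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of a random Dale's-law network ensemble.

    Attributes
    ----------
    N : int
        Neuron count (>= 2).
    f_E : float
        Excitatory fraction, strictly between 0 and 1.  The first
        ``N_E = round(f_E * N)`` neurons are tagged excitatory.
    d : float
        Connection density in (0, 1]; each entry is independently present
        with probability ``d``.
    mu_E, mu_I_mag : float
        Mean excitatory weight and inhibitory weight magnitude (both >= 0);
        inhibitory entries are drawn with mean ``-mu_I_mag``.
    sigma_E, sigma_I : float
        Weight standard deviations (>= 0; zero gives the deterministic
        mean-only ensemble).
    seed : int
        RNG seed; identical spec + seed gives a bitwise-identical matrix.
    """

    N: int = 300
    f_E: float = 0.5
    d: float = 1.0 / 3.0
    mu_E: float = DEFAULT_MU_E
    mu_I_mag: float = DEFAULT_MU_I_MAG
    sigma_E: float = DEFAULT_SIGMA
    sigma_I: float = DEFAULT_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ParameterError(f"N must be >= 2, got {self.N}")
        if not 0.0 < self.f_E < 1.0:
            raise ParameterError(f"f_E must be in (0, 1), got {self.f_E}")
        if not 0.0 < self.d <= 1.0:
            raise ParameterError(f"d must be in (0, 1], got {self.d}")
        if self.mu_E < 0 or self.mu_I_mag < 0:
            raise ParameterError("mean weight magnitudes must be >= 0")
        if self.sigma_E < 0 or self.sigma_I < 0:
            raise ParameterError("weight standard deviations must be >= 0")
        if not 1 <= self.n_excitatory <= self.N - 1:
            raise ParameterError(
                f"round(f_E*N) = {self.n_excitatory} leaves an empty population"
            )

    @property
    def n_excitatory(self) -> int:
        return int(round(self.f_E * self.N))

    @property
    def n_inhibitory(self) -> int:
        return self.N - self.n_excitatory


@dataclass
class WeightMatrix:
    """A structural connectivity matrix with population labels and sparsity mask.

    ``values`` is zero wherever ``mask`` is False.  ``labels`` holds one of
    ``"E"``/``"I"`` per neuron (column population tag).
    """

    values: np.ndarray
    labels: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ParameterError("values must be a square matrix")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("values must be finite")
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.labels.shape != (self.n,):
            raise ParameterError("labels must have one entry per neuron")
        if self.mask is None:
            self.mask = self.values != 0.0
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ParameterError("mask must match values in shape")
        if np.any(self.values[~self.mask] != 0.0):
            raise ParameterError("values must be zero outside the mask")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def is_excitatory(self) -> np.ndarray:
        return self.labels == "E"

    @property
    def n_excitatory(self) -> int:
        return int(np.sum(self.is_excitatory))

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(
            self.values.copy(), self.labels.copy(), self.mask.copy()
        )


def _validate_scalar_args(N: int, sigma: float, d: float) -> None:
    if N < 1:
        raise ParameterError(f"N must be >= 1, got {N}")
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    if not 0.0 < d <= 1.0:
        raise ParameterError(f"d must be in (0, 1], got {d}")


def generate_iid(
    N: int,
    mu: float = 0.0,
    sigma: float = 1.0,
    d: float = 1.0,
    seed: int = 0,
    label: str = "E",
) -> WeightMatrix:
    """Sparse i.i.d. Gaussian matrix: entries present w.p. ``d``, ~N(mu, sigma^2).

    The classic circular-law ensemble (with an outlier at ~``mu*N`` when the
    mean is nonzero).  All neurons carry the single population tag ``label``.
    """
    _validate_scalar_args(N, sigma, d)
    rng = np.random.default_rng(seed)
    mask = rng.random((N, N)) < d
    values = rng.normal(mu, sigma, size=(N, N))
    values[~mask] = 0.0
    labels = np.full(N, label, dtype="<U1")
    return WeightMatrix(values, labels, mask)


def generate_dale(spec: NetworkSpec, clip_to_sign: bool = False) -> WeightMatrix:
    """Dale's-law matrix: E columns ~ N(mu_E, sigma_E^2), I ~ N(-mu_I_mag, sigma_I^2).

    Gaussian weights are not clipped to sign-consistency by default — with
    sigma comparable to the means, individual entries may cross zero while the
    column populations keep their mean signs.  Pass ``clip_to_sign=True`` to
    zero out sign-violating entries.
    """
    rng = np.random.default_rng(spec.seed)
    N, N_E = spec.N, spec.n_excitatory
    mask = rng.random((N, N)) < spec.d
    values = np.empty((N, N))
    values[:, :N_E] = rng.normal(spec.mu_E, spec.sigma_E, size=(N, N_E))
    values[:, N_E:] = rng.normal(-spec.mu_I_mag, spec.sigma_I, size=(N, N - N_E))
    if clip_to_sign:
        values[:, :N_E] = np.maximum(values[:, :N_E], 0.0)
        values[:, N_E:] = np.minimum(values[:, N_E:], 0.0)
    values[~mask] = 0.0
    labels = np.array(["E"] * N_E + ["I"] * (N - N_E), dtype="<U1")
    return WeightMatrix(values, labels, mask)


def balance_rows(W: WeightMatrix) -> WeightMatrix:
    """Rescale each row's inhibitory entries so every row sums to zero.

    Excitatory entries and the sparsity mask are untouched; each row's
    inhibitory entries are multiplied by the single factor that cancels the
    row sum.  The all-ones vector becomes an eigenvector with eigenvalue 0.

    Raises
    ------
    BalancingInfeasibleError
        If a row has a nonzero excitatory sum but no nonzero inhibitory entry.
    """
    is_E = W.is_excitatory
    if not (is_E.any() and (~is_E).any()):
        raise ParameterError("balance_rows requires both E and I neurons")
    values = W.values.copy()
    e_sum = values[:, is_E].sum(axis=1)
    i_sum = values[:, ~is_E].sum(axis=1)
    infeasible = (i_sum == 0.0) & (e_sum != 0.0)
    if np.any(infeasible):
        row = int(np.flatnonzero(infeasible)[0])
        raise BalancingInfeasibleError(
            f"row {row} has excitatory sum {e_sum[row]:g} but no inhibitory "
            "weight to rescale"
        )
    factor = np.ones(W.n)
    nz = i_sum != 0.0
    factor[nz] = -e_sum[nz] / i_sum[nz]
    values[:, ~is_E] *= factor[:, None]
    return WeightMatrix(values, W.labels.copy(), W.mask.copy())


def add_low_rank(W: WeightMatrix, u: np.ndarray, v: np.ndarray) -> WeightMatrix:
    """Add the rank-1 perturbation ``outer(u, v)`` to the weight matrix.

    The mask becomes the union of the old mask and the support of the
    perturbation.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != (W.n,) or v.shape != (W.n,):
        raise ParameterError(
            f"u and v must be length-{W.n} vectors, got {u.shape} and {v.shape}"
        )
    pert = np.outer(u, v)
    values = W.values + pert
    mask = W.mask | (pert != 0.0)
    values = np.where(mask, values, 0.0)
    return WeightMatrix(values, W.labels.copy(), mask)


def diagonal_feedback(W: WeightMatrix, g: float) -> WeightMatrix:
    """Subtract ``g`` from the diagonal (uniform self negative feedback).

    Shifts every eigenvalue by exactly ``-g``.
    """
    if g < 0:
        raise ParameterError(f"g must be >= 0, got {g}")
    if g == 0.0:
        return W.copy()
    values = W.values - g * np.eye(W.n)
    mask = W.mask | np.eye(W.n, dtype=bool)
    return WeightMatrix(values, W.labels.copy(), mask)
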