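"""State-dependent effective connectivity and the full system Jacobian.

The effective connectivity is the x-block of the linearized flow,

    J_eff(x, a, b) = (1/tau_d) * (-I + W B Phi'(h)),

with B = diag(b) (presynaptic depression) and Phi'(h) = diag(phi'(h))
evaluated at the activation argument h = x - a0 - c * sum_k a_k.  Both act
as column scalings of W: depressed or saturated presynaptic neurons
contribute near-zero columns, dynamically sparsifying the network.

``full_jacobian`` assembles the complete linearization over the active state
(x, plus a and b restricted to adapting neurons and enabled mechanisms);
its correctness is guaranteed by a finite-difference oracle test against the
model rhs rather than by any closed-form reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .connectivity import WeightMatrix
from .dynamics import ModelParams, NetworkState, activation_input, phi, phi_prime
from .exceptions import ParameterError

__all__ = [
    "JacobianSnapshot",
    "effective_jacobian",
    "full_jacobian",
    "column_activity_profile",
]


@dataclass
class JacobianSnapshot:
    """The linearization at one instant.

    ``block_index`` maps "x", "a" and "b" to (start, stop) row/column ranges
    of ``J_full``; "a" spans all K timescale blocks (adapting neurons only).
    """

    t: float
    J_eff: np.ndarray
    J_full: np.ndarray
    block_index: Dict[str, Tuple[int, int]]


def _gain_terms(state: NetworkState, W: WeightMatrix, p: ModelParams):
    if W.n != state.n:
        raise ParameterError(f"W is {W.n}x{W.n} but state has N = {state.n}")
    if state.K != p.K:
        raise ParameterError("state and params disagree on K")
    h = activation_input(state, p)
    phip = phi_prime(h, p.w_corner)
    r = phi(h, p.w_corner)
    adapt = p.adapt_mask(W.labels)
    b_eff = np.where(p.std_enabled & adapt, state.b, 1.0)
    return h, r, phip, b_eff, adapt


def effective_jacobian(
    state: NetworkState, W: WeightMatrix, p: ModelParams
) -> np.ndarray:
    """Evaluate J_eff = (1/tau_d)(-I + W B Phi'(h)) at the given state."""
    _, _, phip, b_eff, _ = _gain_terms(state, W, p)
    N = W.n
    return (-np.eye(N) + W.values * (b_eff * phip)[None, :]) / p.tau_d


def full_jacobian(
    state: NetworkState, W: WeightMatrix, p: ModelParams, t: float = 0.0
) -> JacobianSnapshot:
    """Assemble the Jacobian of the full flow over the active coordinates.

    Row/column order: x (all N neurons), then the K SFA blocks restricted to
    adapting neurons (if SFA is enabled), then b restricted to adapting
    neurons (if STD is enabled).  With all adaptation disabled this is just
    J_eff.
    """
    _, r, phip, b_eff, adapt = _gain_terms(state, W, p)
    N, K = W.n, p.K
    idx_a = np.flatnonzero(adapt)
    N_a = idx_a.size
    use_sfa = p.sfa_enabled and N_a > 0
    use_std = p.std_enabled and N_a > 0
    dim = N + (N_a * K if use_sfa else 0) + (N_a if use_std else 0)

    J_eff = (-np.eye(N) + W.values * (b_eff * phip)[None, :]) / p.tau_d
    J = np.zeros((dim, dim))
    J[:N, :N] = J_eff
    block_index = {"x": (0, N)}

    WBphi = W.values * (b_eff * phip)[None, :]
    pos = N
    if use_sfa:
        a_start = pos
        for k, tau in enumerate(p.tau_k):
            sl = slice(pos, pos + N_a)
            # dxdot/da_k: the SFA current shifts the presynaptic neuron's h
            J[:N, sl] = -(p.c / p.tau_d) * WBphi[:, idx_a]
            # dadot_k/dx: adaptation grows with the neuron's own rate
            J[pos + np.arange(N_a), idx_a] = phip[idx_a] / tau
            # dadot_k/da_k': leak plus rate feedback through h
            for k2 in range(K):
                sl2 = slice(a_start + k2 * N_a, a_start + (k2 + 1) * N_a)
                diag = -p.c * phip[idx_a] / tau
                if k2 == k:
                    diag = diag - 1.0 / tau
                J[sl, sl2] += np.diag(diag)
            pos += N_a
        block_index["a"] = (a_start, pos)
    if use_std:
        b_start = pos
        rows = b_start + np.arange(N_a)
        # dxdot/db: synaptic drive scales with the presynaptic rate
        J[:N, b_start : b_start + N_a] = (
            W.values * r[None, :]
        )[:, idx_a] / p.tau_d
        # dbdot/dx: release scales with rate sensitivity
        J[rows, idx_a] = -state.b[idx_a] * phip[idx_a] / p.tau_rel
        if use_sfa:
            a_start = block_index["a"][0]
            for k in range(K):
                cols = a_start + k * N_a + np.arange(N_a)
                J[rows, cols] = p.c * state.b[idx_a] * phip[idx_a] / p.tau_rel
        # dbdot/db: recovery leak plus release at the current rate
        J[rows, rows] = -1.0 / p.tau_rec - r[idx_a] / p.tau_rel
        block_index["b"] = (b_start, b_start + N_a)
        pos += N_a

    return JacobianSnapshot(t=t, J_eff=J_eff, J_full=J, block_index=block_index)


def column_activity_profile(J_eff: np.ndarray, tau_d: float) -> np.ndarray:
    """Euclidean norms of the columns of the recurrent part of J_eff.

    Adds back the leak (I/tau_d) so the profile measures ||column of
    W B Phi' / tau_d||; near-zero entries mark presynaptic neurons silenced
    by saturation or depression (the dynamic column sparsity of the
    effective connectivity).
    """
    J_eff = np.asarray(J_eff, dtype=float)
    N = J_eff.shape[0]
    recurrent = J_eff + np.eye(N) / tau_d
    return np.linalg.norm(recurrent, axis=0)
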