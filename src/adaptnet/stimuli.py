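"""Random-amplitude step stimuli.

The probe used throughout the stability experiments: each targeted neuron
receives a constant input of random amplitude during a single on-window,
and zero outside it.  Amplitudes are drawn i.i.d. Uniform(0, amp_max) on the
target population (excitatory by default) and are zero elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

__all__ = ["StimulusSpec", "random_step", "zero_stimulus", "constant_stimulus"]

#: Default epoch layout (s): 20 baseline, 20 stim, 20 post.
DEFAULT_T_ON = 20.0
DEFAULT_T_OFF = 40.0
DEFAULT_AMP_MAX = 0.5


@dataclass(frozen=True)
class StimulusSpec:
    """A per-neuron step input on the half-open window [t_on, t_off)."""

    t_on: float
    t_off: float
    amplitudes: np.ndarray
    target_population: str = "E"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_on < self.t_off:
            raise ParameterError(
                f"need 0 <= t_on < t_off, got [{self.t_on}, {self.t_off})"
            )
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.ndim != 1:
            raise ParameterError("amplitudes must be a 1-d vector")
        if np.any(amps < 0):
            raise ParameterError("amplitudes must be >= 0")
        object.__setattr__(self, "amplitudes", amps)

    @property
    def n(self) -> int:
        return self.amplitudes.size

    def u(self, t: float) -> np.ndarray:
        """Input vector at time ``t`` (zero outside [t_on, t_off))."""
        if self.t_on <= t < self.t_off:
            return self.amplitudes.copy()
        return np.zeros(self.n)

    def u_array(self, times: np.ndarray) -> np.ndarray:
        """Stimulus evaluated at each time; shape (len(times), N)."""
        times = np.asarray(times, dtype=float)
        on = (times >= self.t_on) & (times < self.t_off)
        return on[:, None] * self.amplitudes[None, :]


def random_step(
    N: int,
    labels: np.ndarray,
    t_on: float = DEFAULT_T_ON,
    t_off: float = DEFAULT_T_OFF,
    amp_max: float = DEFAULT_AMP_MAX,
    seed: int = 0,
    target_population: str = "E",
) -> StimulusSpec:
    """Draw a random-amplitude step stimulus on the target population."""
    if amp_max < 0:
        raise ParameterError(f"amp_max must be >= 0, got {amp_max}")
    labels = np.asarray(labels, dtype="<U1")
    if labels.shape != (N,):
        raise ParameterError("labels must have one entry per neuron")
    target = labels == target_population
    if not target.any():
        raise ParameterError(
            f"no neurons labelled {target_population!r} to stimulate"
        )
    rng = np.random.default_rng(seed)
    amps = np.zeros(N)
    amps[target] = rng.uniform(0.0, amp_max, size=int(target.sum()))
    return StimulusSpec(t_on, t_off, amps, target_population, seed)


def zero_stimulus(N: int, t_on: float = 0.0, t_off: float = np.inf) -> StimulusSpec:
    """An identically-zero input (window irrelevant)."""
    t_off = t_off if np.isfinite(t_off) else 1e30
    return StimulusSpec(t_on, t_off, np.zeros(N))


def constant_stimulus(u: np.ndarray) -> StimulusSpec:
    """A constant input applied for all time (for fixed-point analyses)."""
    return StimulusSpec(0.0, 1e30, np.asarray(u, dtype=float))
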