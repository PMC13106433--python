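"""Eigenvalue analysis and random-matrix-theory predictions.

Thin, typed wrappers over numpy's nonsymmetric eigensolver plus the
circular-law radius formula and an outlier counter.  Eigenvalues are sorted
lexicographically by (real, imag) so spectra of related matrices can be
matched elementwise (e.g. for diagonal-shift tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .connectivity import WeightMatrix
from .exceptions import ParameterError

__all__ = [
    "EigenSpectrum",
    "eigenvalues",
    "spectral_radius",
    "spectral_abscissa",
    "circular_law_radius",
    "count_outliers",
]


@dataclass(frozen=True)
class EigenSpectrum:
    """Full spectrum of a real square matrix.

    ``predicted_radius`` optionally carries the circular-law radius of the
    generating ensemble for downstream outlier tests.
    """

    eigenvalues: np.ndarray
    source_shape: int
    predicted_radius: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "eigenvalues", np.asarray(self.eigenvalues, dtype=complex)
        )
        if self.eigenvalues.shape != (self.source_shape,):
            raise ParameterError("eigenvalue count must equal source_shape")

    def shifted(self, delta: complex) -> "EigenSpectrum":
        return EigenSpectrum(
            _lexsorted(self.eigenvalues + delta),
            self.source_shape,
            self.predicted_radius,
        )


def _lexsorted(vals: np.ndarray) -> np.ndarray:
    order = np.lexsort((vals.imag, vals.real))
    return vals[order]


def _as_matrix(M) -> np.ndarray:
    if isinstance(M, WeightMatrix):
        M = M.values
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ParameterError(f"expected a square matrix, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ParameterError("matrix entries must be finite")
    return M


def eigenvalues(M, predicted_radius: Optional[float] = None) -> EigenSpectrum:
    """Full eigenspectrum of a square real matrix (or WeightMatrix)."""
    M = _as_matrix(M)
    vals = _lexsorted(np.linalg.eigvals(M))
    return EigenSpectrum(vals, M.shape[0], predicted_radius)


def _spectrum_values(s) -> np.ndarray:
    vals = s.eigenvalues if isinstance(s, EigenSpectrum) else np.asarray(s, complex)
    if vals.size == 0:
        raise ParameterError("empty spectrum")
    return vals


def spectral_radius(s) -> float:
    """Maximum eigenvalue modulus."""
    return float(np.max(np.abs(_spectrum_values(s))))


def spectral_abscissa(s) -> float:
    """Maximum eigenvalue real part (negative implies linear stability)."""
    return float(np.max(_spectrum_values(s).real))


def circular_law_radius(sigma: float, N: int, d: float = 1.0) -> float:
    """Circular-law bulk radius ``sigma * sqrt(N * d)``.

    Invariant to N when the expected indegree N*d is held constant.
    """
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    if N < 1 or not 0 < d <= 1:
        raise ParameterError("need N >= 1 and 0 < d <= 1")
    return float(sigma * np.sqrt(N * d))


def count_outliers(
    s, radius: float, tol: float = 0.05
) -> Tuple[int, np.ndarray]:
    """Eigenvalues outside the bulk disk: ``|lambda| > radius * (1 + tol)``.

    The tolerance absorbs finite-N edge fluctuations (which scale like
    N^(-1/2)); 5% is conservative for N >= 200.
    """
    if radius < 0 or tol < 0:
        raise ParameterError("radius and tol must be >= 0")
    vals = _spectrum_values(s)
    outliers = vals[np.abs(vals) > radius * (1.0 + tol)]
    return int(outliers.size), outliers
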