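"""Serialization helpers: portable array containers with JSON sidecars,
and CSV export for spectra, Lyapunov traces and sweep tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .connectivity import NetworkSpec, WeightMatrix
from .dynamics import Trajectory
from .lyapunov import LyapunovTrace
from .spectra import EigenSpectrum

__all__ = [
    "save_weight_matrix",
    "load_weight_matrix",
    "weight_matrix_to_csv",
    "spectrum_to_csv",
    "trace_to_csv",
    "save_trajectory",
]


def save_weight_matrix(
    W: WeightMatrix, path: str, spec: Optional[NetworkSpec] = None
) -> None:
    """Write values/labels/mask to ``<path>.npz`` plus a JSON sidecar with
    the generating spec (if provided)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), values=W.values, labels=W.labels,
             mask=W.mask)
    meta = {"n": W.n, "n_excitatory": W.n_excitatory}
    if spec is not None:
        meta["spec"] = asdict(spec)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_weight_matrix(path: str) -> WeightMatrix:
    data = np.load(Path(path).with_suffix(".npz"))
    return WeightMatrix(data["values"], data["labels"], data["mask"])


def weight_matrix_to_csv(W: WeightMatrix, path: str) -> None:
    """Dense CSV export (small matrices only)."""
    pd.DataFrame(W.values, columns=W.labels).to_csv(path, index=False)


def spectrum_to_csv(s: EigenSpectrum, path: str) -> None:
    pd.DataFrame(
        {"re": s.eigenvalues.real, "im": s.eigenvalues.imag}
    ).to_csv(path, index=False)


def trace_to_csv(trace: LyapunovTrace, path: str) -> None:
    df = pd.DataFrame(
        {"time": trace.times, "log_expansion": trace.log_expansions}
    )
    local = pd.Series(np.nan, index=df.index)
    local.iloc[trace._window_count - 1 :] = trace.lambda1_local
    df["lambda1_local"] = local
    df.to_csv(path, index=False)


def save_trajectory(traj: Trajectory, path: str, meta: Optional[dict] = None) -> None:
    path = Path(path)
    np.savez(
        path.with_suffix(".npz"),
        times=traj.times,
        x=traj.x,
        a=traj.a,
        b=traj.b,
        rates=traj.rates,
        stimulus=traj.stimulus,
    )
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
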