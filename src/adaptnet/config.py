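"""Run configuration: YAML files mirroring the model, network, stimulus and
Lyapunov-estimator parameter sets field for field."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .connectivity import NetworkSpec
from .dynamics import ModelParams
from .experiments import SweepSettings

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    model: ModelParams = field(default_factory=ModelParams)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    sweep: SweepSettings = field(default_factory=SweepSettings)
    amp_max: float = 0.5
    t_on: float = 20.0
    t_off: float = 40.0
    n_networks: int = 25
    f_E_min: float = 0.4
    f_E_max: float = 0.6

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "RunConfig":
        def build(klass, section):
            known = {f.name for f in fields(klass)}
            unknown = set(section) - known
            if unknown:
                raise ValueError(
                    f"unknown {klass.__name__} fields: {sorted(unknown)}"
                )
            return klass(**section)

        kwargs: Dict[str, Any] = {}
        if "model" in d:
            kwargs["model"] = build(ModelParams, d["model"])
        if "network" in d:
            kwargs["network"] = build(NetworkSpec, d["network"])
        if "sweep" in d:
            kwargs["sweep"] = build(SweepSettings, d["sweep"])
        for key in ("amp_max", "t_on", "t_off", "n_networks",
                    "f_E_min", "f_E_max"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    def to_dict(self) -> Dict[str, Any]:
        return {
            "model": asdict(self.model),
            "network": asdict(self.network),
            "sweep": asdict(self.sweep),
            "amp_max": self.amp_max,
            "t_on": self.t_on,
            "t_off": self.t_off,
            "n_networks": self.n_networks,
            "f_E_min": self.f_E_min,
            "f_E_max": self.f_E_max,
        }


def load_config(path: Optional[str]) -> RunConfig:
    """Load a YAML run configuration; None gives all defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(data)
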