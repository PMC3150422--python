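"""Run configuration: strict YAML/JSON serialization of simulation setups.

A :class:`RunConfig` mirrors :class:`~rirrsim.engine.SimulationParams` plus
the layout selection and output options. Loading is strict: unknown keys
anywhere in the document are rejected, and configurations round-trip
losslessly through ``to_dict`` / ``from_dict``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import SimulationParams
from .exceptions import ParameterError
from .geometry import CellGeometry, make_layout
from .particles import KineticParams
from .respiration import LeakageRuleParams


@dataclass
class LayoutConfig:
    """Which layout to build and with what options (seeded, reproducible)."""

    name: str = "regular"
    options: dict = field(default_factory=dict)  # forwarded to the constructor

    def build(self) -> CellGeometry:
        return make_layout(self.name, **self.options)


@dataclass
class RunConfig:
    """Full description of a simulation run."""

    layout: LayoutConfig = field(default_factory=LayoutConfig)
    params: SimulationParams = field(default_factory=SimulationParams)
    outdir: str = "rirr_out"
    render_every: int = 0  # 0 disables snapshot rendering
    render_enzymes: bool = False

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _from_dict(cls, d, path="")

    def dump(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=1)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


def _from_dict(cls, d: dict, path: str):
    if not isinstance(d, dict):
        raise ParameterError(f"expected a mapping at {path or 'top level'}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise ParameterError(f"unknown config keys at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in d.items():
        ftype = fields[name].type
        nested = _NESTED.get((cls.__name__, name))
        if nested is not None and value is not None:
            kwargs[name] = _from_dict(nested, value, f"{path}{name}.")
        elif name == "membrane_cross" and isinstance(value, dict):
            kwargs[name] = {k: tuple(v) for k, v in value.items()}
        else:
            kwargs[name] = value
    obj = cls(**kwargs)
    return obj


_NESTED = {
    ("RunConfig", "layout"): LayoutConfig,
    ("RunConfig", "params"): SimulationParams,
    ("SimulationParams", "kinetics"): KineticParams,
    ("SimulationParams", "leakage"): LeakageRuleParams,
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    cfg = RunConfig.from_dict(data or {})
    cfg.params.validate()
    if cfg.render_every < 0:
        raise ParameterError("render_every must be >= 0")
    return cfg
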