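"""Run configuration: YAML/JSON blocks for parameters, protocol settings
and the bifurcation scans, with strict unknown-key rejection and a
resolved-config echo for exact reproducibility."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .parameters import ModelParameters
from .protocol import STRATEGIES, ProtocolSpec

__all__ = ["RunConfig", "BifurcationConfig"]

_PRESET_NAMES = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class BifurcationConfig:
    """Scan windows for the one-parameter sweeps and the cusp search."""

    G_scan: tuple[float, float] = (0.0, 1.0)
    S_scan: tuple[float, float] = (0.0, 0.5)
    S_fixed: float = 0.2
    G_fixed: float = 0.45

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "BifurcationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown bifurcation keys: {sorted(unknown)}")
        kw = dict(data)
        for k in ("G_scan", "S_scan"):
            if k in kw:
                kw[k] = tuple(float(v) for v in kw[k])
        return cls(**kw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "G_scan": list(self.G_scan),
            "S_scan": list(self.S_scan),
            "S_fixed": self.S_fixed,
            "G_fixed": self.G_fixed,
        }


_PROTOCOL_FIELDS = {f.name for f in dataclasses.fields(ProtocolSpec)} - {"strategy"}


@dataclass
class RunConfig:
    """Top-level configuration of a reproduction run."""

    parameters: ModelParameters = field(default_factory=ModelParameters)
    protocol: dict[str, Any] = field(default_factory=dict)
    bifurcation: BifurcationConfig = field(default_factory=BifurcationConfig)
    strategies: tuple[str, ...] = STRATEGIES
    presets: tuple[str, ...] = _PRESET_NAMES
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        for s in self.strategies:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")
        for q in self.presets:
            if q not in _PRESET_NAMES:
                raise ValueError(f"unknown preset {q!r}")
        unknown = set(self.protocol) - _PROTOCOL_FIELDS
        if unknown:
            raise KeyError(f"unknown protocol keys: {sorted(unknown)}")

    def protocol_spec(self, strategy: str) -> ProtocolSpec:
        return ProtocolSpec(strategy=strategy, **self.protocol)

    # -- serialisation -------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {"parameters", "protocol", "bifurcation", "strategies", "presets", "seed", "verbosity"}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        kw: dict[str, Any] = {}
        if "parameters" in data:
            base = ModelParameters().to_dict()
            base.update(data["parameters"] or {})
            kw["parameters"] = ModelParameters.from_dict(base)
        if "protocol" in data:
            kw["protocol"] = dict(data["protocol"] or {})
        if "bifurcation" in data:
            kw["bifurcation"] = BifurcationConfig.from_dict(data["bifurcation"] or {})
        for k in ("seed", "verbosity"):
            if k in data:
                kw[k] = data[k]
        for k in ("strategies", "presets"):
            if k in data:
                kw[k] = tuple(data[k])
        return cls(**kw)

    def to_dict(self) -> dict[str, Any]:
        """Fully resolved configuration (all defaults materialised)."""
        proto = {f.name: getattr(ProtocolSpec(strategy="tgfb_only"), f.name) for f in dataclasses.fields(ProtocolSpec)}
        proto.pop("strategy")
        proto.update(self.protocol)
        return {
            "parameters": self.parameters.to_dict(),
            "protocol": proto,
            "bifurcation": self.bifurcation.to_dict(),
            "strategies": list(self.strategies),
            "presets": list(self.presets),
            "seed": self.seed,
            "verbosity": self.verbosity,
        }

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
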