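"""Structured run configuration with strict key checking.

One YAML document holds the sub-configurations of every stage; unknown keys
are rejected with the offending name so typos fail loudly rather than being
silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .decompose import DEFAULT_BANDS
from .srrn import SRRNConfig
from .stmap import PreprocessConfig
from .synth import SynthConfig
from .train import TrainPlan

__all__ = ["RunConfig", "ConfigError"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class BandsConfig:
    edges: list = field(default_factory=lambda: [list(b) for b in DEFAULT_BANDS])
    fps: float = 30.0


@dataclass
class RunConfig:
    schema_version: int = SCHEMA_VERSION
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    bands: BandsConfig = field(default_factory=BandsConfig)
    network: SRRNConfig = field(default_factory=SRRNConfig)
    training: TrainPlan = field(default_factory=TrainPlan)
    synthesis: SynthConfig = field(default_factory=SynthConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("top-level config must be a mapping")
        known = {f.name: f for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                raise ConfigError(f"unknown config key: {key}")
        kwargs = {}
        for name, f in known.items():
            if name not in raw:
                continue
            sub = raw[name]
            if dataclasses.is_dataclass(f.type) or name in (
                    "preprocess", "bands", "network", "training", "synthesis"):
                sub_cls = {"preprocess": PreprocessConfig,
                           "bands": BandsConfig,
                           "network": SRRNConfig,
                           "training": TrainPlan,
                           "synthesis": SynthConfig}.get(name)
                if sub_cls is None:
                    kwargs[name] = sub
                    continue
                if not isinstance(sub, dict):
                    raise ConfigError(f"config section {name!r} must be a mapping")
                sub_known = {sf.name for sf in dataclasses.fields(sub_cls)}
                for k in sub:
                    if k not in sub_known:
                        raise ConfigError(
                            f"unknown config key: {name}.{k}")
                coerced = {
                    k: (tuple(tuple(x) if isinstance(x, list) else x
                              for x in v) if isinstance(v, list) and
                        name != "bands" else v)
                    for k, v in sub.items()
                }
                kwargs[name] = sub_cls(**coerced)
            else:
                kwargs[name] = sub
        return cls(**kwargs)
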