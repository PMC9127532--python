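"""Run configuration: YAML/JSON parsing with validation and defaults.

The configuration mirrors :class:`qwpso.engine.QwpsoConfig` plus the
method selector. Unknown keys are rejected by name; an empty file yields
the all-defaults configuration.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import yaml

from .engine import QwpsoConfig
from .qpso import QpsoParams
from .types import ClusterParams, InputError, ParameterError
from .wormhole import WormholeParams


class ConfigError(ValueError):
    """A configuration file violates the schema."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with defaults filled in."""

    method: str = "qwpso"
    seed: int = 0
    polarity: str = "bright-object"
    qpso: QpsoParams = field(default_factory=QpsoParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    wormhole: WormholeParams = field(default_factory=WormholeParams)

    def __post_init__(self) -> None:
        if self.method not in ("qpso", "qwpso"):
            raise ConfigError(f"method must be 'qpso' or 'qwpso', got {self.method!r}")

    def engine_config(self, seed: int | None = None) -> QwpsoConfig:
        return QwpsoConfig(
            qpso=self.qpso,
            cluster=self.cluster,
            wormhole=self.wormhole,
            polarity=self.polarity,
            seed=self.seed if seed is None else seed,
            wormhole_enabled=(self.method == "qwpso"),
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "polarity": self.polarity,
            "qpso": asdict(self.qpso),
            "cluster": asdict(self.cluster),
            "wormhole": asdict(self.wormhole),
        }


_SECTIONS = {"qpso": QpsoParams, "cluster": ClusterParams, "wormhole": WormholeParams}
_TOP_KEYS = {"method", "seed", "polarity", "qpso", "cluster", "wormhole"}


def config_from_dict(data: dict) -> RunConfig:
    """Build a validated RunConfig from a (possibly partial) nested dict."""
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        valid = set(cls.__dataclass_fields__)
        bad = set(section) - valid
        if bad:
            raise ConfigError(f"unknown key(s) in section {name!r}: {', '.join(sorted(bad))}")
        try:
            kwargs[name] = cls(**section)
        except ParameterError as exc:
            raise ConfigError(f"invalid value in section {name!r}: {exc}") from exc
    for key in ("method", "seed", "polarity"):
        if key in data:
            kwargs[key] = data[key]
    try:
        return RunConfig(**kwargs)
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc


def parse_config(path: str | os.PathLike) -> RunConfig:
    """Parse a YAML or JSON configuration file."""
    if not os.path.exists(path):
        raise InputError(f"configuration file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        return RunConfig()
    if str(path).endswith(".json"):
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"invalid JSON in {path}: {exc}") from exc
    else:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if data is None:
        return RunConfig()
    return config_from_dict(data)


def serialize_config(cfg: RunConfig) -> str:
    """YAML text that reparses (via parse_config) to an equal config."""
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True)
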