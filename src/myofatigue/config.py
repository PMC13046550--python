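"""Run configuration: YAML/JSON round-trippable, strict about unknown keys.

Every command writes a resolved copy of its configuration next to its
outputs so any artifact can be regenerated from the copy plus the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict

import yaml

from .parameters import ModelParameters

__all__ = ["RunConfig", "load_config", "save_config"]

_PROTOCOL_KEYS = {"n_cycles", "T_cyc", "T_on", "output_dt", "rtol", "atol",
                  "iemg_start", "iemg_end", "profile_kind"}


@dataclass
class RunConfig:
    parameters: Dict[str, float] = field(default_factory=dict)
    protocol: Dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    n_starts: int = 100
    n_samples: int = 10_000
    out_dir: str = "out"

    def __post_init__(self) -> None:
        # resolving the parameter overrides also validates them (positivity)
        self.model_parameters()
        unknown = set(self.protocol) - _PROTOCOL_KEYS
        if unknown:
            raise KeyError(f"unknown protocol keys: {sorted(unknown)}")

    def model_parameters(self) -> ModelParameters:
        base = ModelParameters().to_dict()
        for key, value in self.parameters.items():
            if key not in base:
                raise KeyError(f"unknown model parameter: {key!r}")
            base[key] = value
        return ModelParameters.from_dict(base)

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Read a YAML or JSON run configuration, filling defaults.

    Raises on unknown keys, malformed files and invalid parameter values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as err:
        raise ValueError(f"{path}: malformed config: {err}") from err
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise KeyError(f"{path}: unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
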