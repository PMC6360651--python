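"""Run configuration: constants and the reporting rounding contract.

Rounding digits apply only at the reporting/rendering layer; every
computation is carried out at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .model import DEFAULT_EFFECTIVENESS, STERILITY_ADJUSTMENT, TOTAL_FECUNDITY

__all__ = ["ModelConfig", "load_config"]


@dataclass(frozen=True)
class ModelConfig:
    effectiveness: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTIVENESS)
    )
    total_fecundity: float = TOTAL_FECUNDITY
    sterility_adjustment: float = STERILITY_ADJUSTMENT
    index_digits: int = 3
    tfr_digits: int = 3
    percent_digits: int = 1
    projection_digits: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "effectiveness", dict(self.effectiveness))
        if self.total_fecundity <= 0:
            raise ValueError("total_fecundity must be > 0")
        for method, e in self.effectiveness.items():
            if not (0.0 <= e <= 1.0):
                raise ValueError(f"effectiveness for {method!r} must lie in [0, 1]")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        if "effectiveness" in data:
            # partial tables override the defaults method by method
            merged = dict(DEFAULT_EFFECTIVENESS)
            merged.update(data["effectiveness"])
            data = {**data, "effectiveness": merged}
        return replace(base, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return {
            "effectiveness": dict(self.effectiveness),
            "total_fecundity": self.total_fecundity,
            "sterility_adjustment": self.sterility_adjustment,
            "index_digits": self.index_digits,
            "tfr_digits": self.tfr_digits,
            "percent_digits": self.percent_digits,
            "projection_digits": self.projection_digits,
        }


def load_config(path: str | Path | None) -> ModelConfig:
    """Load a YAML config, or return the defaults when ``path`` is None."""
    if path is None:
        return ModelConfig()
    return ModelConfig.from_yaml(path)
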