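"""Pipeline configuration (TOML) and run manifests."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig", "config_hash"]


@dataclass
class PipelineConfig:
    """End-to-end run settings; everything is seeded through ``seed``."""

    seed: int = 0
    n_leads: int = 612
    voxel_size_mm: float = 0.25
    scenarios: list[str] = field(
        default_factory=lambda: ["implanted_only", "plus2mm", "plus4mm", "plus6mm"]
    )
    extensions_mm: list[float] = field(default_factory=lambda: [2.0, 4.0, 6.0])
    contact_sphere_radius_mm: float = 1.0
    vat_radius_mm: float = 2.0
    label_scenario: str = "plus6mm"  # scenario defining classifier labels
    cv_folds: int = 5
    confidence_threshold: float = 0.95
    gpc_restarts: int = 2
    grid: dict[str, list[float]] = field(
        default_factory=lambda: {
            "x": [-1.0, 3.0, 0.5],
            "y": [-2.0, 2.0, 0.5],
            "ms": [10.0, 35.0, 1.0],
            "acpc": [35.0, 65.0, 1.0],
        }
    )
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.contact_sphere_radius_mm <= 0 or self.vat_radius_mm <= 0:
            raise ValueError("sphere radii must be positive")
        from .engagement import SCENARIOS

        for s in self.scenarios + [self.label_scenario]:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: PipelineConfig) -> str:
    """Stable sha256 of the canonicalized configuration."""
    canon = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()
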