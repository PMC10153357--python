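"""Run configuration: population kinetics, file references, seeds, hashing.

Population effective half-lives for the Madsen method are runtime
configuration per structure -- the shipped defaults are clearly-editable
placeholders (they simply echo the synthetic generator's median kinetics) and
every report records the values actually used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .stp_estimators import PopulationKinetics

__all__ = [
    "DEFAULT_POPULATION_HALFLIVES",
    "population_kinetics_from_mapping",
    "RunConfig",
    "config_hash",
]

#: Placeholder population effective half-lives (hours) per structure; edit to
#: your clinic's values before interpreting Madsen-method results.
DEFAULT_POPULATION_HALFLIVES: dict[str, float] = {
    "healthy_liver": 65.0,
    "left_kidney": 50.0,
    "right_kidney": 50.0,
    "kidney": 50.0,
    "spleen": 70.0,
    "tumor": 90.0,
}


def population_kinetics_from_mapping(
    halflives: Mapping[str, float] | None = None,
) -> dict[str, PopulationKinetics]:
    """Build the structure -> PopulationKinetics map from a half-life mapping."""
    hl = dict(DEFAULT_POPULATION_HALFLIVES if halflives is None else halflives)
    return {s: PopulationKinetics(s, float(T)) for s, T in hl.items()}


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    canonical = json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


@dataclass
class RunConfig:
    """Declarative configuration for a pipeline run (YAML or JSON file)."""

    seed: int = 0
    population_halflives_h: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_HALFLIVES)
    )
    noise: dict | None = None  # {"a":..., "b":...} | {"fit_from": csv path} | None
    n_curves: int = 250
    families: tuple[str, ...] = ("hanscheid", "madsen", "2tp", "3tp")
    invalid_policy: str = "exclude"
    penalty_percent: float = 200.0
    ci_method: str = "normal"

    def __post_init__(self) -> None:
        if self.invalid_policy not in ("exclude", "penalize"):
            raise ValueError(f"unknown invalid policy {self.invalid_policy!r}")
        if self.ci_method not in ("normal", "t"):
            raise ValueError(f"unknown CI method {self.ci_method!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "families" in data:
            data["families"] = tuple(data["families"])
        return cls(**data)

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "population_halflives_h": self.population_halflives_h,
            "noise": self.noise,
            "n_curves": self.n_curves,
            "families": list(self.families),
            "invalid_policy": self.invalid_policy,
            "penalty_percent": self.penalty_percent,
            "ci_method": self.ci_method,
        }

    @property
    def hash(self) -> str:
        return config_hash(self.to_json())
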