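"""Closed-form single-time-point (STP) estimators of time-integrated activity.

Two widely used STP approximations for post-therapy dosimetry:

* Hänscheid:  TIA = A(t) * 2t / ln 2.  Derived from a monoexponential
  approximation; exact when the sampling time equals the structure's effective
  half-life (and again at twice the half-life), with a maximum overestimate of
  ``2/(e ln 2) - 1`` (about +6.15%) at ``t = T_eff/ln 2`` on monoexponential
  kinetics.
* Madsen:  TIA = A(t) * exp(lambda_pop t) / lambda_pop, using a population-
  average effective decay constant; exact whenever the patient's kinetics equal
  the population average, with relative error
  ``(lambda/lambda_pop) exp((lambda_pop - lambda) t) - 1`` otherwise.

Population half-lives are runtime configuration per structure, never constants:
see :mod:`redtia.config` for the editable placeholder defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .tac_models import STRUCTURES, TimeActivitySample

__all__ = [
    "PopulationKinetics",
    "hanscheid_tia",
    "madsen_tia",
    "hanscheid_tia_at",
    "madsen_tia_at",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class PopulationKinetics:
    """Population-average effective half-life for one structure."""

    structure: str
    T_pop: float  # hours

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if not (np.isfinite(self.T_pop) and self.T_pop > 0):
            raise ValueError(f"population half-life must be positive, got {self.T_pop}")

    @property
    def lambda_pop(self) -> float:
        """Effective decay constant ln2 / T_pop in 1/h."""
        return _LN2 / self.T_pop


def hanscheid_tia_at(time, activity):
    """Vectorized Hänscheid estimate A(t) * 2t / ln2 (MBq·h)."""
    t = np.asarray(time, dtype=float)
    a = np.asarray(activity, dtype=float)
    if np.any(t <= 0):
        raise ValueError("sampling time must be positive")
    if np.any(a < 0):
        raise ValueError("activity must be >= 0")
    return a * 2.0 * t / _LN2


def madsen_tia_at(time, activity, lambda_pop: float):
    """Vectorized Madsen estimate A(t) exp(lambda_pop t) / lambda_pop (MBq·h)."""
    t = np.asarray(time, dtype=float)
    a = np.asarray(activity, dtype=float)
    if np.any(t <= 0):
        raise ValueError("sampling time must be positive")
    if np.any(a < 0):
        raise ValueError("activity must be >= 0")
    if not lambda_pop > 0:
        raise ValueError("lambda_pop must be positive")
    return a * np.exp(lambda_pop * t) / lambda_pop


def hanscheid_tia(sample: TimeActivitySample) -> float:
    """Hänscheid single-time-point TIA estimate for one measurement."""
    return float(hanscheid_tia_at(sample.time, sample.activity))


def madsen_tia(sample: TimeActivitySample, pop: PopulationKinetics) -> float:
    """Madsen single-time-point TIA estimate using population kinetics."""
    return float(madsen_tia_at(sample.time, sample.activity, pop.lambda_pop))


def lookup_population_kinetics(
    kinetics: Mapping[str, PopulationKinetics], structure: str
) -> PopulationKinetics:
    """Fetch the configured kinetics for a structure, raising a config error if absent."""
    try:
        return kinetics[structure]
    except KeyError:
        raise KeyError(
            f"no population kinetics configured for structure {structure!r}"
        ) from None
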