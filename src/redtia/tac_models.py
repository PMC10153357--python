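"""Exponential time-activity-curve models and their analytic time-integrated activity.

Activity in a structure after administration of a radiopharmaceutical is modelled as
either a monoexponential washout ``A(t) = C exp(-lambda t)`` or a biexponential
uptake-and-washout ``A(t) = C (exp(-lambda1 t) - exp(-lambda2 t))`` with
``lambda2 > lambda1 > 0``.  All decay constants are *effective* (biological plus
physical) rates in 1/h; amplitudes are in MBq and times in hours post-injection.

The time-integrated activity (TIA) is the integral of A(t) over [0, inf), the
quantity multiplied by S-values to obtain absorbed dose.  For these model families
it has a closed form: ``C/lambda`` (mono) and ``C (1/lambda1 - 1/lambda2)`` (bi).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "STRUCTURES",
    "ExponentialModel",
    "TimeActivitySample",
    "TimeActivityCurve",
]

#: Structure labels used throughout the package.  "kidney" is the pooled
#: left+right label used when deriving cohort distributions.
STRUCTURES = (
    "healthy_liver",
    "left_kidney",
    "right_kidney",
    "kidney",
    "spleen",
    "tumor",
)


@dataclass(frozen=True)
class ExponentialModel:
    """A mono- or biexponential time-activity model.

    Parameters
    ----------
    kind:
        ``"mono"`` or ``"bi"``.
    C:
        Amplitude in MBq; must be positive.
    lambda1:
        Effective decay constant in 1/h (the single rate when mono); positive.
    lambda2:
        Second (uptake) rate in 1/h, required iff ``kind == "bi"`` and strictly
        greater than ``lambda1`` so that the activity is non-negative for t >= 0
        and the TIA is finite and positive.
    """

    kind: str
    C: float
    lambda1: float
    lambda2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mono", "bi"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not (np.isfinite(self.C) and self.C > 0):
            raise ValueError(f"amplitude C must be positive and finite, got {self.C}")
        if not (np.isfinite(self.lambda1) and self.lambda1 > 0):
            raise ValueError(f"lambda1 must be positive and finite, got {self.lambda1}")
        if self.kind == "mono":
            if self.lambda2 is not None:
                raise ValueError("mono model must not carry lambda2")
        else:
            if self.lambda2 is None or not np.isfinite(self.lambda2):
                raise ValueError("bi model requires a finite lambda2")
            if not self.lambda2 > self.lambda1:
                raise ValueError(
                    "bi model requires lambda2 > lambda1 "
                    f"(got lambda1={self.lambda1}, lambda2={self.lambda2})"
                )

    def activity(self, t):
        """Evaluate A(t) at time(s) ``t`` (hours, >= 0).  Accepts scalars or arrays."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time must be >= 0")
        if self.kind == "mono":
            out = self.C * np.exp(-self.lambda1 * t_arr)
        else:
            out = self.C * (np.exp(-self.lambda1 * t_arr) - np.exp(-self.lambda2 * t_arr))
        if np.isscalar(t) or np.ndim(t) == 0:
            return float(out)
        return out

    def tia(self) -> float:
        """Analytic time-integrated activity in MBq·h (integral of A over [0, inf))."""
        if self.kind == "mono":
            return self.C / self.lambda1
        return self.C * (1.0 / self.lambda1 - 1.0 / self.lambda2)

    # -- serialization -------------------------------------------------------

    def to_json(self) -> dict:
        rec = {"kind": self.kind, "C_MBq": self.C, "lambda1_per_h": self.lambda1}
        if self.kind == "bi":
            rec["lambda2_per_h"] = self.lambda2
        return rec

    @classmethod
    def from_json(cls, rec: Mapping) -> "ExponentialModel":
        return cls(
            kind=rec["kind"],
            C=float(rec["C_MBq"]),
            lambda1=float(rec["lambda1_per_h"]),
            lambda2=float(rec["lambda2_per_h"]) if rec.get("lambda2_per_h") is not None else None,
        )


def evaluate_activity(model: ExponentialModel, t):
    """Functional alias for :meth:`ExponentialModel.activity`."""
    return model.activity(t)


def analytic_tia(model: ExponentialModel) -> float:
    """Functional alias for :meth:`ExponentialModel.tia`."""
    return model.tia()


@dataclass(frozen=True, order=True)
class TimeActivitySample:
    """One (time, activity) measurement: hours post-injection and MBq."""

    time: float
    activity: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise ValueError(f"sample time must be positive, got {self.time}")
        if not (np.isfinite(self.activity) and self.activity >= 0):
            raise ValueError(f"activity must be >= 0, got {self.activity}")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Measured time-activity data for one structure of one patient.

    ``roi`` is an instance label distinguishing multiple lesions that share the
    same structure type (e.g. ``tumor_2``); it defaults to the structure name.
    """

    patient_id: str
    structure: str
    samples: tuple[TimeActivitySample, ...]
    roi: str = ""

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        samples = tuple(self.samples)
        object.__setattr__(self, "samples", samples)
        if len(samples) < 1:
            raise ValueError("curve needs at least one sample")
        times = [s.time for s in samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        if not self.roi:
            object.__setattr__(self, "roi", self.structure)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.samples])

    @property
    def activities(self) -> np.ndarray:
        return np.array([s.activity for s in self.samples])
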