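"""Power-law SPECT measurement-noise model fit from repeat phantom imaging.

Repeat quantification of phantom objects at several scan lengths yields, per
(object, scan length) group, a relative standard deviation RSD = SD/mean and an
"effective activity": the activity that would have produced the same number of
detected decays at a 25-minute reference scan, ``A_eff = A * L / 25``.  Shorter
scans therefore stand in for the lower count rates of later imaging days.

The noise model is the power law ``RSD(A_eff) = a * A_eff^b`` fit by ordinary
least squares on the log-log transformed group data.  It supplies the standard
deviation (RSD * A) of the Gaussian noise injected about each sampled point of
a simulated time-activity curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PhantomMeasurement",
    "NoiseModel",
    "effective_activity",
    "fit_noise_power_law",
    "apply_noise",
    "REFERENCE_SCAN_LENGTH_MIN",
]

#: Reference scan length (minutes) to which effective activities are normalized.
REFERENCE_SCAN_LENGTH_MIN = 25.0


@dataclass(frozen=True)
class PhantomMeasurement:
    """One repeat activity quantification of one phantom object."""

    object_label: str
    scan_length: float  # minutes
    repeat_index: int
    activity: float  # MBq

    def __post_init__(self) -> None:
        if not self.scan_length > 0:
            raise ValueError("scan length must be positive")
        if self.activity < 0:
            raise ValueError("activity must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """RSD(A) = a * A^b with a > 0; RSD is fractional (SD/mean), not percent."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError(f"power-law coefficient a must be positive, got {self.a}")
        if not np.isfinite(self.b):
            raise ValueError("power-law exponent b must be finite")

    def rsd(self, activity):
        """Relative standard deviation at the given activity (MBq, > 0)."""
        a_arr = np.asarray(activity, dtype=float)
        with np.errstate(divide="ignore"):
            return self.a * np.power(a_arr, self.b)

    def sd(self, activity):
        """Absolute standard deviation RSD(A) * A in MBq; 0 at A = 0."""
        a_arr = np.asarray(activity, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(a_arr > 0, self.a * np.power(a_arr, self.b) * a_arr, 0.0)
        if np.ndim(activity) == 0:
            return float(out)
        return out

    def to_json(self) -> dict:
        return {"a": self.a, "b": self.b}

    @classmethod
    def from_json(cls, rec) -> "NoiseModel":
        return cls(a=float(rec["a"]), b=float(rec["b"]))


def effective_activity(
    activity: float, scan_length: float, reference_length: float = REFERENCE_SCAN_LENGTH_MIN
):
    """Rescale an activity to the decay-count-equivalent at the reference scan length."""
    if np.any(np.asarray(scan_length) <= 0):
        raise ValueError("scan length must be positive")
    if np.any(np.asarray(activity) < 0):
        raise ValueError("activity must be >= 0")
    return activity * scan_length / reference_length


def fit_noise_power_law(measurements: Iterable[PhantomMeasurement]) -> NoiseModel:
    """Fit RSD = a * A_eff^b from grouped repeat phantom measurements.

    Per (object, scan length) group the sample RSD (ddof=1) and the mean
    effective activity are computed; groups with zero mean or zero spread are
    excluded with a warning (their log is undefined).  The coefficients come
    from ordinary least squares of ln(RSD) on ln(A_eff).
    """
    groups: dict[tuple[str, float], list[float]] = {}
    for m in measurements:
        groups.setdefault((m.object_label, m.scan_length), []).append(m.activity)

    log_aeff, log_rsd = [], []
    for (label, length), acts in sorted(groups.items()):
        arr = np.asarray(acts, dtype=float)
        if arr.size < 2:
            warnings.warn(f"group ({label!r}, {length} min) has <2 repeats; excluded")
            continue
        mean = float(arr.mean())
        if mean <= 0:
            warnings.warn(f"group ({label!r}, {length} min) has non-positive mean; excluded")
            continue
        rsd = float(arr.std(ddof=1)) / mean
        if rsd <= 0:
            warnings.warn(f"group ({label!r}, {length} min) has zero spread; excluded")
            continue
        log_aeff.append(np.log(effective_activity(mean, length)))
        log_rsd.append(np.log(rsd))

    if len(log_aeff) < 2:
        raise ValueError("fewer than 2 usable (object, scan length) groups")
    fit = stats.linregress(log_aeff, log_rsd)
    return NoiseModel(a=float(np.exp(fit.intercept)), b=float(fit.slope))


def apply_noise(true_activity, model: NoiseModel, rng: np.random.Generator, floor: float = 0.0):
    """Draw a noisy measured activity about the true sampled activity.

    Gaussian with mean = true activity and sd = RSD(true) * true; draws below
    ``floor`` are clamped (keeping the draw count deterministic per point).
    Zero true activity has zero absolute noise under the multiplicative model.
    """
    a_arr = np.asarray(true_activity, dtype=float)
    if np.any(a_arr < 0):
        raise ValueError("activity must be >= 0")
    draw = rng.normal(a_arr, model.sd(a_arr))
    out = np.maximum(draw, floor)
    if np.ndim(true_activity) == 0:
        return float(out)
    return out
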