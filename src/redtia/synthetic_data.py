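"""Synthetic clinical-like cohorts and phantom repeat-measurement tables.

No clinical or phantom data ships with the package; this module generates
both study inputs programmatically:

* a cohort of virtual patients, each with healthy liver, left/right kidney,
  spleen and 1-5 tumors, imaged once inside each of the four nominal windows
  (~4, 24, 96, 168 h post-injection, jittered within 3-5 / 21-52 / 71-126 /
  144-194 h), with measurement noise applied to the sampled activities and the
  generating ground-truth models returned separately (sealed truth, read only
  by tests and validation);
* repeat phantom measurement tables (4 repeats per object and scan length,
  10 scan lengths spanning a 16-fold count reduction) whose spread follows a
  known power law, for exercising the noise-model fit.

Default kinetics are plausible-placeholder values for post-therapy
Lu-177-DOTATATE (effective half-lives: kidney ~50 h, healthy liver ~65 h,
spleen ~70 h, tumor ~90 h) and are plain configuration -- edit them freely;
nothing downstream assumes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .noise_model import (
    NoiseModel,
    PhantomMeasurement,
    REFERENCE_SCAN_LENGTH_MIN,
    effective_activity,
)
from .cohort_simulation import LognormalSpec
from .schedule_enumeration import DEFAULT_TIME_PERIODS, TimePeriod
from .tac_models import ExponentialModel, TimeActivityCurve, TimeActivitySample

__all__ = [
    "StructureKinetics",
    "SyntheticCohortConfig",
    "DEFAULT_STRUCTURE_KINETICS",
    "DEFAULT_NOISE_MODEL",
    "generate_clinical_cohort",
    "generate_phantom_table",
    "DEFAULT_PHANTOM_SCAN_LENGTHS",
    "DEFAULT_PHANTOM_ACTIVITIES",
]

#: Default measurement-noise power law: counting-statistics exponent (-1/2)
#: with ~1% repeatability at 100 MBq effective activity.
DEFAULT_NOISE_MODEL = NoiseModel(a=0.10, b=-0.5)


@dataclass(frozen=True)
class StructureKinetics:
    """Generating kinetics for one structure (editable placeholders).

    ``T_eff_h`` is the median effective half-life of the slow (washout) phase,
    ``C_MBq`` the median amplitude; ``s_lambda``/``s_C`` are lognormal spreads
    of the log, ``bi_fraction`` the probability of a biexponential (uptake)
    curve whose fast rate is centred on ``uptake_T_h``.
    """

    T_eff_h: float
    C_MBq: float
    s_lambda: float = 0.3
    s_C: float = 0.5
    bi_fraction: float = 0.3
    uptake_T_h: float = 2.0
    s_lambda2: float = 0.3

    def __post_init__(self) -> None:
        if not (self.T_eff_h > 0 and self.C_MBq > 0 and self.uptake_T_h > 0):
            raise ValueError("half-lives and amplitude must be positive")
        if not (0 <= self.bi_fraction <= 1):
            raise ValueError("bi_fraction must lie in [0, 1]")
        if min(self.s_lambda, self.s_C, self.s_lambda2) < 0:
            raise ValueError("spreads must be >= 0")


#: Plausible-placeholder kinetics per structure.  Amplitudes follow the
#: configured concentration ordering liver > spleen > kidney > tumor.
DEFAULT_STRUCTURE_KINETICS: dict[str, StructureKinetics] = {
    "healthy_liver": StructureKinetics(T_eff_h=65.0, C_MBq=250.0),
    "left_kidney": StructureKinetics(T_eff_h=50.0, C_MBq=90.0),
    "right_kidney": StructureKinetics(T_eff_h=50.0, C_MBq=85.0),
    "spleen": StructureKinetics(T_eff_h=70.0, C_MBq=120.0),
    "tumor": StructureKinetics(T_eff_h=90.0, C_MBq=60.0),
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Configuration of the synthetic clinical-like cohort."""

    n_patients: int = 28
    tumors_per_patient: tuple[int, int] = (1, 5)
    kinetics: Mapping[str, StructureKinetics] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURE_KINETICS)
    )
    windows: tuple[TimePeriod, ...] = DEFAULT_TIME_PERIODS
    noise: NoiseModel | None = DEFAULT_NOISE_MODEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        lo, hi = self.tumors_per_patient
        if not 0 <= lo <= hi:
            raise ValueError("invalid tumors_per_patient range")
        if "tumor" not in self.kinetics:
            raise ValueError("kinetics must include 'tumor'")
        lows = [w.low for w in self.windows]
        if any(b <= a for a, b in zip(lows, lows[1:])):
            raise ValueError("windows must be increasing")


def _truncated(mu: float, s: float, width: float = 3.5) -> LognormalSpec:
    if s == 0:
        return LognormalSpec(s=0.0, mu=mu, lower=mu, upper=mu)
    return LognormalSpec(s=s, mu=mu, lower=mu * math.exp(-width * s),
                         upper=mu * math.exp(width * s))


def _draw_model(k: StructureKinetics, rng: np.random.Generator) -> ExponentialModel:
    lam1_spec = _truncated(math.log(2) / k.T_eff_h, k.s_lambda)
    C_spec = _truncated(k.C_MBq, k.s_C)
    if rng.random() < k.bi_fraction:
        lam2_spec = _truncated(math.log(2) / k.uptake_T_h, k.s_lambda2)
        C = C_spec.sample(rng)
        for _ in range(100_000):
            l1 = lam1_spec.sample(rng)
            l2 = lam2_spec.sample(rng)
            if l2 > l1:
                return ExponentialModel("bi", C, l1, l2)
        raise RuntimeError("uptake rate never exceeded washout rate; check config")
    return ExponentialModel("mono", C_spec.sample(rng), lam1_spec.sample(rng))


def generate_clinical_cohort(
    cfg: SyntheticCohortConfig,
) -> tuple[list[TimeActivityCurve], dict[tuple[str, str], ExponentialModel]]:
    """Generate observed curves plus the sealed ground-truth models.

    Returns ``(curves, truth)`` where ``truth[(patient_id, roi)]`` is the
    generating model of that curve.  Scan times are drawn uniformly inside
    each of the four windows; noise (if configured) is applied to each sampled
    activity and negative draws are clamped to zero.
    """
    root = np.random.SeedSequence(cfg.seed)
    curves: list[TimeActivityCurve] = []
    truth: dict[tuple[str, str], ExponentialModel] = {}
    lo, hi = cfg.tumors_per_patient
    for pidx, pseq in enumerate(root.spawn(cfg.n_patients)):
        rng = np.random.default_rng(pseq)
        pid = f"P{pidx + 1:03d}"
        rois: list[tuple[str, str]] = [
            (s, s) for s in cfg.kinetics if s != "tumor"
        ]
        n_tum = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        rois.extend(("tumor", f"tumor_{j + 1}") for j in range(n_tum))
        for structure, roi in rois:
            model = _draw_model(cfg.kinetics[structure], rng)
            times = np.array([rng.uniform(w.low, w.high) for w in cfg.windows])
            acts = model.activity(times)
            if cfg.noise is not None:
                acts = np.maximum(rng.normal(acts, cfg.noise.sd(acts)), 0.0)
            samples = tuple(
                TimeActivitySample(float(t), float(a)) for t, a in zip(times, acts)
            )
            curves.append(TimeActivityCurve(pid, structure, samples, roi=roi))
            truth[(pid, roi)] = model
    return curves, truth


#: Ten scan lengths spanning a 16-fold count reduction below the 25-min
#: reference -- a stand-in for ~10 days of physical + biological decay.
DEFAULT_PHANTOM_SCAN_LENGTHS: tuple[float, ...] = tuple(
    round(REFERENCE_SCAN_LENGTH_MIN * (1 / 16) ** (k / 9), 4) for k in range(10)
)

#: Seven synthetic phantom-object activities (MBq) spanning the range from a
#: high-uptake organ insert down to a small low-concentration insert.
DEFAULT_PHANTOM_ACTIVITIES: tuple[float, ...] = (310.0, 195.0, 67.0, 45.0, 27.0, 13.0, 8.5)


def generate_phantom_table(
    noise_truth: NoiseModel | None,
    scan_lengths: Sequence[float] = DEFAULT_PHANTOM_SCAN_LENGTHS,
    n_repeats: int = 4,
    object_activities: Sequence[float] = DEFAULT_PHANTOM_ACTIVITIES,
    seed: int = 0,
) -> list[PhantomMeasurement]:
    """Simulate repeat phantom quantification under a known noise power law.

    For each (object, scan length), ``n_repeats`` activities are drawn about
    the object's true activity with SD = RSD(effective activity) * activity.
    ``noise_truth=None`` produces exact repeats (a degenerate table on which
    the power-law fit must fail -- zero spread in every group).
    """
    if len(scan_lengths) < 2:
        raise ValueError("need at least 2 scan lengths")
    if any(a <= 0 for a in object_activities):
        raise ValueError("object activities must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: list[PhantomMeasurement] = []
    for oidx, act in enumerate(object_activities):
        label = f"object_{oidx + 1}"
        for length in scan_lengths:
            if noise_truth is None:
                draws = np.full(n_repeats, act)
            else:
                aeff = effective_activity(act, length)
                sd = float(noise_truth.rsd(aeff)) * act
                draws = np.maximum(rng.normal(act, sd, size=n_repeats), 0.0)
            out.extend(
                PhantomMeasurement(label, float(length), r, float(a))
                for r, a in enumerate(draws)
            )
    return out
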