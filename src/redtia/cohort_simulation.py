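"""Virtual-patient simulation: cohort parameter distributions and the Monte-Carlo study.

The simulated cohort mirrors a clinical one in two steps.  First, per
structure, the 4-point reference fits of the (real or synthetic) clinical
cohort define a :class:`CohortDistribution`: the observed mono/bi fit-type
labels (the bootstrap source) and, per exponential parameter, a truncated
lognormal with ``s`` = SD of the natural log of the cohort values and ``mu`` =
exp of the mean of the natural log, truncated to the cohort min/max -- widened,
for the slow decay constant, to any broader literature effective-half-life
range supplied as a cutoff.  Second, simulated time-activity curves are drawn:
fit type bootstrapped from the labels, parameters sampled from their truncated
lognormals (biexponential rates jointly resampled until lambda2 > lambda1).

:func:`run_simulation_study` then sweeps every requested schedule family over
``n_curves`` simulated curves per structure, with measurement noise injected
about each sampled point, and records the TIA estimate of the matching method
(Hänscheid / Madsen closed forms, exact 2-point fit, 3-point least-squares
monoexponential) against the analytic TIA of the generating model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curve_fitting import FitResult, fit_mono_batch
from .error_analysis import summarize_arrays
from .noise_model import NoiseModel
from .schedule_enumeration import enumerate_2tp, enumerate_3tp, stp_grid
from .stp_estimators import (
    PopulationKinetics,
    hanscheid_tia_at,
    lookup_population_kinetics,
    madsen_tia_at,
)
from .tac_models import ExponentialModel

__all__ = [
    "LognormalSpec",
    "CohortDistribution",
    "derive_distribution",
    "sample_tac",
    "SimulationResult",
    "run_simulation_study",
]

_MAX_REJECTION_TRIES = 100_000


@dataclass(frozen=True)
class LognormalSpec:
    """Truncated lognormal for one exponential parameter.

    ``s`` is the SD of the natural log of the cohort values; ``mu`` the exp of
    their mean log (the geometric mean, which always lies inside the
    truncation bounds derived from the cohort range).
    """

    s: float
    mu: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.s >= 0:
            raise ValueError("s must be >= 0")
        if not 0 < self.lower <= self.mu <= self.upper:
            raise ValueError(
                f"bounds must satisfy 0 < lower <= mu <= upper "
                f"(got lower={self.lower}, mu={self.mu}, upper={self.upper})"
            )

    def sample(self, rng: np.random.Generator) -> float:
        """Rejection-sample the truncated lognormal (exact; cap guards misconfiguration)."""
        if self.s == 0:
            return self.mu
        logmu = math.log(self.mu)
        for _ in range(_MAX_REJECTION_TRIES):
            x = math.exp(rng.normal(logmu, self.s))
            if self.lower <= x <= self.upper:
                return x
        raise RuntimeError("rejection sampling failed; inconsistent truncation bounds")

    def to_json(self) -> dict:
        return {"s": self.s, "mu": self.mu, "lower": self.lower, "upper": self.upper}

    @classmethod
    def from_json(cls, rec) -> "LognormalSpec":
        return cls(s=float(rec["s"]), mu=float(rec["mu"]),
                   lower=float(rec["lower"]), upper=float(rec["upper"]))


@dataclass(frozen=True)
class CohortDistribution:
    """Per-structure generating distribution derived from reference fits."""

    structure: str
    fit_type_labels: tuple[str, ...]
    mono: Mapping[str, LognormalSpec] | None  # keys: C, lambda1
    bi: Mapping[str, LognormalSpec] | None  # keys: C, lambda1, lambda2

    def __post_init__(self) -> None:
        if not self.fit_type_labels:
            raise ValueError("fit_type_labels must be nonempty")
        for lab in self.fit_type_labels:
            if lab not in ("mono", "bi"):
                raise ValueError(f"unknown fit type {lab!r}")
            if getattr(self, lab) is None:
                raise ValueError(f"label {lab!r} present but no {lab} parameter specs")

    def bi_fraction(self) -> float:
        return sum(1 for l in self.fit_type_labels if l == "bi") / len(self.fit_type_labels)

    def to_json(self) -> dict:
        return {
            "structure": self.structure,
            "fit_type_labels": list(self.fit_type_labels),
            "mono": {k: v.to_json() for k, v in self.mono.items()} if self.mono else None,
            "bi": {k: v.to_json() for k, v in self.bi.items()} if self.bi else None,
        }

    @classmethod
    def from_json(cls, rec) -> "CohortDistribution":
        return cls(
            structure=rec["structure"],
            fit_type_labels=tuple(rec["fit_type_labels"]),
            mono={k: LognormalSpec.from_json(v) for k, v in rec["mono"].items()}
            if rec.get("mono") else None,
            bi={k: LognormalSpec.from_json(v) for k, v in rec["bi"].items()}
            if rec.get("bi") else None,
        )


def _spec_from_values(values: Sequence[float], lower=None, upper=None) -> LognormalSpec:
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("parameter values must be positive for lognormal derivation")
    logs = np.log(arr)
    s = float(logs.std(ddof=1)) if arr.size >= 2 else 0.0
    mu = float(np.exp(logs.mean()))
    lo = float(arr.min()) if lower is None else min(float(arr.min()), lower)
    hi = float(arr.max()) if upper is None else max(float(arr.max()), upper)
    mu = min(max(mu, lo), hi)  # geometric mean is inside the range up to roundoff
    return LognormalSpec(s=s, mu=mu, lower=lo, upper=hi)


def derive_distribution(
    fits: Sequence[FitResult],
    structure: str,
    halflife_cutoffs: tuple[float, float] | None = None,
) -> CohortDistribution:
    """Derive the per-structure generating distribution from reference fits.

    ``halflife_cutoffs = (T_low, T_high)`` in hours widens the truncation of
    the slow decay constant (mono lambda, bi lambda1) when the literature range
    exceeds the cohort's: lower bound min(cohort min, ln2/T_high), upper bound
    max(cohort max, ln2/T_low).  Fit types with fewer than 2 reference fits are
    dropped from the bootstrap source (with a warning).
    """
    valid = [f for f in fits if f.valid and f.model is not None]
    if not valid:
        raise ValueError("no valid reference fits for distribution derivation")
    by_kind: dict[str, list[ExponentialModel]] = {"mono": [], "bi": []}
    for f in valid:
        by_kind[f.model.kind].append(f.model)

    lam_lo = math.log(2) / halflife_cutoffs[1] if halflife_cutoffs else None
    lam_hi = math.log(2) / halflife_cutoffs[0] if halflife_cutoffs else None

    labels: list[str] = []
    mono_specs = bi_specs = None
    for kind, models in by_kind.items():
        if not models:
            continue
        if len(models) < 2:
            warnings.warn(
                f"structure {structure!r}: only {len(models)} {kind} reference fit(s); "
                "fit type dropped from bootstrap source"
            )
            continue
        labels.extend([kind] * len(models))
        C = [m.C for m in models]
        l1 = [m.lambda1 for m in models]
        if kind == "mono":
            mono_specs = {
                "C": _spec_from_values(C),
                "lambda1": _spec_from_values(l1, lower=lam_lo, upper=lam_hi),
            }
        else:
            bi_specs = {
                "C": _spec_from_values(C),
                "lambda1": _spec_from_values(l1, lower=lam_lo, upper=lam_hi),
                "lambda2": _spec_from_values([m.lambda2 for m in models]),
            }
    if not labels:
        raise ValueError(f"structure {structure!r}: no fit type with >= 2 reference fits")
    return CohortDistribution(
        structure=structure, fit_type_labels=tuple(labels), mono=mono_specs, bi=bi_specs
    )


def sample_tac(dist: CohortDistribution, rng: np.random.Generator) -> ExponentialModel:
    """Draw one simulated ground-truth model from the cohort distribution.

    The fit type is a uniform draw (with replacement) from the observed
    labels; biexponential rates are jointly resampled until lambda2 > lambda1
    so neither marginal is distorted by swapping.
    """
    kind = dist.fit_type_labels[int(rng.integers(len(dist.fit_type_labels)))]
    if kind == "mono":
        specs = dist.mono
        return ExponentialModel("mono", specs["C"].sample(rng), specs["lambda1"].sample(rng))
    specs = dist.bi
    C = specs["C"].sample(rng)
    for _ in range(_MAX_REJECTION_TRIES):
        l1 = specs["lambda1"].sample(rng)
        l2 = specs["lambda2"].sample(rng)
        if l2 > l1:
            return ExponentialModel("bi", C, l1, l2)
    raise RuntimeError("could not draw lambda2 > lambda1; inconsistent distributions")


# -- the Monte-Carlo study ---------------------------------------------------

_FAMILIES = ("hanscheid", "madsen", "2tp", "3tp")


@dataclass
class SimulationResult:
    """Estimate matrices for one simulation run.

    Per structure and method family: ``schedules`` (list of time tuples),
    ``est``/``valid`` matrices of shape (n_curves, n_schedules) and the
    per-curve ground-truth TIA vector.
    """

    seed: int
    n_curves: int
    structures: tuple[str, ...]
    true_tia: dict[str, np.ndarray]
    schedules: dict[str, list[tuple[float, ...]]]  # per family (shared across structures)
    est: dict[tuple[str, str], np.ndarray]  # (structure, family) -> matrix
    valid: dict[tuple[str, str], np.ndarray]
    metadata: dict = field(default_factory=dict)

    def summaries(
        self, invalid_policy: str = "exclude", penalty_percent: float = 200.0,
        ci_method: str = "normal",
    ) -> pd.DataFrame:
        """One row per (structure, method, schedule) with the cohort error metrics."""
        frames = []
        for (structure, family), est in sorted(self.est.items()):
            stats = summarize_arrays(
                est, self.true_tia[structure], self.valid[(structure, family)],
                invalid_policy=invalid_policy, penalty_percent=penalty_percent,
                ci_method=ci_method,
            )
            scheds = self.schedules[family]
            df = pd.DataFrame(
                {
                    "structure": structure,
                    "method": family,
                    "t1_h": [s[0] for s in scheds],
                    "t2_h": [s[1] if len(s) > 1 else np.nan for s in scheds],
                    "t3_h": [s[2] if len(s) > 2 else np.nan for s in scheds],
                    **stats,
                }
            )
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_records(self) -> pd.DataFrame:
        """Long per-estimate table (structure, curve_id, method, times, truth,
        estimate, validity).  Sizeable for full runs; intended for modest
        ``n_curves`` or downstream CSV export."""
        frames = []
        for (structure, family), est in sorted(self.est.items()):
            scheds = self.schedules[family]
            n_c, n_s = est.shape
            true = np.repeat(self.true_tia[structure], n_s)
            df = pd.DataFrame(
                {
                    "structure": structure,
                    "curve_id": np.repeat(np.arange(n_c), n_s),
                    "method": family,
                    "t1_h": np.tile([s[0] for s in scheds], n_c),
                    "t2_h": np.tile([s[1] if len(s) > 1 else np.nan for s in scheds], n_c),
                    "t3_h": np.tile([s[2] if len(s) > 2 else np.nan for s in scheds], n_c),
                    "tia_true_MBq_h": true,
                    "tia_est_MBq_h": est.ravel(),
                    "valid": self.valid[(structure, family)].ravel(),
                }
            )
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def run_simulation_study(
    dists: Mapping[str, CohortDistribution],
    population_kinetics: Mapping[str, PopulationKinetics] | None = None,
    noise: NoiseModel | None = None,
    n_curves: int = 250,
    seed: int = 0,
    families: Sequence[str] = _FAMILIES,
) -> SimulationResult:
    """Sweep all requested schedule families over a simulated cohort.

    For each structure, ``n_curves`` ground-truth models are drawn and their
    activity evaluated on the hourly grid 1..240 h; one Gaussian noise
    realization per grid point (clamped at zero) is shared by every schedule
    touching that point, as all grids are subsets of the hourly one.  The
    random stream is hierarchical (seed -> structure -> curve), so adding
    schedule families never perturbs curve generation.  Fully reproducible
    from ``seed``.
    """
    for fam in families:
        if fam not in _FAMILIES:
            raise ValueError(f"unknown schedule family {fam!r}")
    if "madsen" in families and population_kinetics is None:
        raise ValueError("madsen family requires population kinetics")

    grid = np.arange(1.0, 241.0)
    structures = tuple(sorted(dists))
    root = np.random.SeedSequence(seed)
    struct_seqs = root.spawn(len(structures))

    schedules: dict[str, list[tuple[float, ...]]] = {}
    if "hanscheid" in families or "madsen" in families:
        stp_times = np.asarray(stp_grid(), dtype=float)
        stp_sched = [(float(t),) for t in stp_times]
        if "hanscheid" in families:
            schedules["hanscheid"] = stp_sched
        if "madsen" in families:
            schedules["madsen"] = list(stp_sched)
    if "2tp" in families:
        pairs = [s.times for s in enumerate_2tp()]
        schedules["2tp"] = pairs
        p_t1 = np.array([p[0] for p in pairs])
        p_t2 = np.array([p[1] for p in pairs])
        p_i1 = (p_t1 - 1).astype(int)
        p_i2 = (p_t2 - 1).astype(int)
    if "3tp" in families:
        trips = [s.times for s in enumerate_3tp()]
        schedules["3tp"] = trips
        tr_t = np.array(trips, dtype=float)  # (S, 3)
        tr_i = (tr_t - 1).astype(int)

    true_tia: dict[str, np.ndarray] = {}
    est: dict[tuple[str, str], np.ndarray] = {}
    valid: dict[tuple[str, str], np.ndarray] = {}

    for structure, sseq in zip(structures, struct_seqs):
        dist = dists[structure]
        A = np.empty((n_curves, grid.size))
        tia = np.empty(n_curves)
        for i, cseq in enumerate(sseq.spawn(n_curves)):
            rng = np.random.default_rng(cseq)
            model = sample_tac(dist, rng)
            tia[i] = model.tia()
            a_true = model.activity(grid)
            if noise is not None:
                A[i] = np.maximum(rng.normal(a_true, noise.sd(a_true)), 0.0)
            else:
                A[i] = a_true
        true_tia[structure] = tia

        if "hanscheid" in families:
            est[(structure, "hanscheid")] = hanscheid_tia_at(grid[None, :], A)
            valid[(structure, "hanscheid")] = np.ones_like(A, dtype=bool)
        if "madsen" in families:
            lam_pop = lookup_population_kinetics(population_kinetics, structure).lambda_pop
            est[(structure, "madsen")] = madsen_tia_at(grid[None, :], A, lam_pop)
            valid[(structure, "madsen")] = np.ones_like(A, dtype=bool)
        if "2tp" in families:
            A1, A2 = A[:, p_i1], A[:, p_i2]
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                lam = np.log(A1 / A2) / (p_t2 - p_t1)
                ok = (A1 > 0) & (A2 > 0) & np.isfinite(lam) & (lam > 0)
                lam_safe = np.where(ok, lam, 1.0)
                C = A1 * np.exp(np.clip(lam_safe * p_t1, None, 700.0))
                e2 = np.where(ok, C / lam_safe, np.nan)
            est[(structure, "2tp")] = e2
            valid[(structure, "2tp")] = ok
        if "3tp" in families:
            a3 = A[:, tr_i].reshape(-1, 3)
            t3 = np.broadcast_to(tr_t, (n_curves, *tr_t.shape)).reshape(-1, 3)
            fit = fit_mono_batch(t3, a3)
            est[(structure, "3tp")] = fit["tia"].reshape(n_curves, -1)
            valid[(structure, "3tp")] = fit["valid"].reshape(n_curves, -1)

    meta = {
        "seed": seed,
        "n_curves": n_curves,
        "families": list(families),
        "noise": noise.to_json() if noise is not None else None,
        "population_halflives_h": {
            s: population_kinetics[s].T_pop for s in structures
        } if population_kinetics is not None else None,
    }
    return SimulationResult(
        seed=seed, n_curves=n_curves, structures=structures, true_tia=true_tia,
        schedules=schedules, est=est, valid=valid, metadata=meta,
    )
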