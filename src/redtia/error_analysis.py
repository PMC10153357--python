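"""Error metrics of TIA estimates versus ground truth and optimal-schedule search.

For each sampling schedule the cohort of percent errors
``100 (TIA_est - TIA_true) / TIA_true`` is summarized by its mean (MPE), sample
standard deviation (SD), mean absolute value (MAPE) and, on the absolute TIA
scale, the root-mean-square error (RMSE, MBq·h).  The optimal schedule for a
structure and method is the one with the lowest RMSE across the cohort.

Estimates flagged invalid (non-positive fitted decay constant, floored-zero
activities) are by default excluded from the metric means but counted in
``n_total``; the "penalize" policy instead substitutes a configurable percent
error cap so that failure-prone schedules surface in RMSE rankings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "ErrorSummary",
    "percent_error",
    "summarize",
    "summarize_arrays",
    "find_optimal_schedule",
    "build_reports",
]


@dataclass(frozen=True)
class ErrorSummary:
    """Cohort error metrics for one (structure, method, schedule)."""

    n_total: int
    n_valid: int
    rmse: float  # MBq·h
    mpe: float  # percent
    sd: float  # percent, sample (n-1) SD of percent errors
    mape: float  # percent
    ci95_low: float  # percent, confidence interval for the mean percent error
    ci95_high: float

    def to_json(self) -> dict:
        return asdict(self)


def percent_error(tia_est: float, tia_true: float) -> float:
    """Signed percent error 100 (est - true) / true; true must be positive."""
    if not tia_true > 0:
        raise ValueError(f"true TIA must be positive, got {tia_true}")
    return 100.0 * (tia_est - tia_true) / tia_true


def _ci_halfwidth(sd: float, n: int, method: str) -> float:
    if n < 2 or not np.isfinite(sd):
        return float("nan")
    if method == "t":
        z = float(_sps.t.ppf(0.975, n - 1))
    else:
        z = 1.96
    return z * sd / math.sqrt(n)


def summarize(
    records: Iterable[tuple[float, float, bool]],
    invalid_policy: str = "exclude",
    penalty_percent: float = 200.0,
    ci_method: str = "normal",
) -> ErrorSummary:
    """Summarize (tia_est, tia_true, valid) records into an :class:`ErrorSummary`.

    ``invalid_policy="exclude"`` drops invalid records from the metrics (they
    still count in ``n_total``); ``"penalize"`` replaces each invalid estimate
    by ``true * (1 + penalty_percent/100)``.
    """
    recs = list(records)
    n_total = len(recs)
    if invalid_policy not in ("exclude", "penalize"):
        raise ValueError(f"unknown invalid policy {invalid_policy!r}")
    est, true = [], []
    n_valid = 0
    for e, t, v in recs:
        if v:
            n_valid += 1
            est.append(e)
            true.append(t)
        elif invalid_policy == "penalize":
            est.append(t * (1.0 + penalty_percent / 100.0))
            true.append(t)
    if not est:
        raise ValueError("no valid records to summarize")
    est_a = np.asarray(est, dtype=float)
    true_a = np.asarray(true, dtype=float)
    if np.any(true_a <= 0):
        raise ValueError("true TIA must be positive")
    pe = 100.0 * (est_a - true_a) / true_a
    n = pe.size
    mpe = float(pe.mean())
    sd = float(pe.std(ddof=1)) if n >= 2 else float("nan")
    mape = float(np.abs(pe).mean())
    rmse = float(np.sqrt(np.mean((est_a - true_a) ** 2)))
    hw = _ci_halfwidth(sd, n, ci_method)
    return ErrorSummary(
        n_total=n_total, n_valid=n_valid, rmse=rmse, mpe=mpe, sd=sd, mape=mape,
        ci95_low=mpe - hw, ci95_high=mpe + hw,
    )


def summarize_arrays(
    est: np.ndarray,
    true: np.ndarray,
    valid: np.ndarray,
    invalid_policy: str = "exclude",
    penalty_percent: float = 200.0,
    ci_method: str = "normal",
) -> dict[str, np.ndarray]:
    """Vectorized :func:`summarize` over schedules.

    ``est`` and ``valid`` have shape (n_curves, n_schedules); ``true`` has
    shape (n_curves,).  Returns per-schedule metric arrays.  Schedules with no
    valid estimate get NaN metrics rather than raising.
    """
    est = np.asarray(est, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    true = np.asarray(true, dtype=float)[:, None]
    if invalid_policy == "penalize":
        est = np.where(valid, est, true * (1.0 + penalty_percent / 100.0))
        use = np.ones_like(valid, dtype=bool)
    else:
        use = valid
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN schedule columns
        pe = np.where(use, 100.0 * (est - true) / true, np.nan)
        sq = np.where(use, (est - true) ** 2, np.nan)
        n_used = use.sum(axis=0)
        mpe = np.nanmean(pe, axis=0)
        sd = np.where(n_used >= 2, np.nanstd(pe, axis=0, ddof=1), np.nan)
        mape = np.nanmean(np.abs(pe), axis=0)
        rmse = np.sqrt(np.nanmean(sq, axis=0))
        if ci_method == "t":
            z = np.where(n_used >= 2, _sps.t.ppf(0.975, np.maximum(n_used - 1, 1)), np.nan)
        else:
            z = 1.96
        hw = z * sd / np.sqrt(np.maximum(n_used, 1))
    return {
        "n_total": np.full(est.shape[1], est.shape[0]),
        "n_valid": valid.sum(axis=0),
        "rmse": rmse,
        "mpe": mpe,
        "sd": sd,
        "mape": mape,
        "ci95_low": mpe - hw,
        "ci95_high": mpe + hw,
    }


def find_optimal_schedule(summaries: Mapping) -> object:
    """Key (schedule) with the minimal RMSE; exact ties break to the
    lexicographically earliest time tuple."""
    if not summaries:
        raise ValueError("no summaries given")
    def rmse_of(v):
        return v.rmse if isinstance(v, ErrorSummary) else float(v["rmse"])
    return min(sorted(summaries, key=_schedule_key), key=lambda k: rmse_of(summaries[k]))


def _schedule_key(k):
    if hasattr(k, "times"):
        return tuple(k.times)
    if isinstance(k, (tuple, list)):
        return tuple(k)
    return (k,)


_TIME_COLS = ["t1_h", "t2_h", "t3_h"]


def build_reports(summary_df: pd.DataFrame, metadata: Mapping | None = None) -> dict:
    """Assemble report tables from a per-schedule summary table.

    ``summary_df`` must carry columns structure, method, t1_h, t2_h, t3_h,
    n_total, n_valid, rmse, mpe, sd, mape.  Returns a dict with:

    * ``"optimal"``: one row per structure x method -- the lowest-RMSE schedule
      with its metrics (the published optimal-schedule table layout);
    * ``"heatmap_mpe"`` / ``"heatmap_sd"``: per structure, the 2TP metric as an
      upper-triangular t1 x t2 matrix (heatmap export);
    * ``"metadata"``: run provenance (seed, config hash, population
      half-lives) echoed into every report.
    """
    df = summary_df.copy()
    rows = []
    for (structure, method), grp in df.groupby(["structure", "method"], sort=True):
        grp = grp.sort_values(_TIME_COLS, na_position="first")
        best = grp.loc[grp["rmse"].idxmin()] if grp["rmse"].notna().any() else None
        # idxmin returns the first occurrence in row order -> lexicographic tie-break
        if best is None:
            continue
        rows.append(
            {
                "structure": structure,
                "method": method,
                "optimal_times_h": "/".join(
                    f"{best[c]:g}" for c in _TIME_COLS if pd.notna(best[c])
                ),
                "rmse_MBq_h": best["rmse"],
                "mpe_pct": best["mpe"],
                "sd_pct": best["sd"],
                "mape_pct": best["mape"],
                "n_valid": int(best["n_valid"]),
                "n_total": int(best["n_total"]),
            }
        )
    optimal = pd.DataFrame(rows)

    heat_mpe: dict[str, pd.DataFrame] = {}
    heat_sd: dict[str, pd.DataFrame] = {}
    two = df[df["method"] == "2tp"]
    for structure, grp in two.groupby("structure"):
        heat_mpe[structure] = grp.pivot(index="t1_h", columns="t2_h", values="mpe")
        heat_sd[structure] = grp.pivot(index="t1_h", columns="t2_h", values="sd")

    return {
        "optimal": optimal,
        "heatmap_mpe": heat_mpe,
        "heatmap_sd": heat_sd,
        "metadata": dict(metadata or {}),
    }
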