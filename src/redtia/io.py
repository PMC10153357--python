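"""CSV/TSV/JSON readers and writers for the pipeline's tabular artifacts.

Schemas (header mandatory, UTF-8, LF, decimal point):

* time-activity CSV: ``patient_id, structure, time_h, activity_MBq`` with an
  optional ``roi`` column distinguishing multiple lesions of one structure;
* phantom CSV: ``object_label, scan_length_min, repeat_index, activity_MBq``;
* schedule CSV: ``t1_h, t2_h, t3_h`` (blank trailing slots);
* JSON artifacts (noise model, cohort distributions, reference fits) carry
  full precision; report CSVs are written at 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort_simulation import CohortDistribution
from .curve_fitting import FitResult
from .noise_model import NoiseModel, PhantomMeasurement
from .schedule_enumeration import SamplingSchedule
from .tac_models import TimeActivityCurve, TimeActivitySample

__all__ = [
    "SchemaError",
    "read_time_activity_csv",
    "write_time_activity_csv",
    "read_phantom_csv",
    "write_phantom_csv",
    "write_schedules_csv",
    "read_json",
    "write_json",
    "write_report_csv",
    "FLOAT_FORMAT",
]

#: Fixed float formatting for report CSVs (6 significant digits) -- makes
#: repeated runs byte-comparable.
FLOAT_FORMAT = "%.6g"


class SchemaError(ValueError):
    """An input file does not match its declared schema."""


_TA_COLUMNS = ["patient_id", "structure", "time_h", "activity_MBq"]
_PH_COLUMNS = ["object_label", "scan_length_min", "repeat_index", "activity_MBq"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_time_activity_csv(path: str | Path) -> list[TimeActivityCurve]:
    """Read a time-activity CSV into curves grouped by (patient, roi)."""
    df = pd.read_csv(path)
    _require_columns(df, _TA_COLUMNS, path)
    if "roi" not in df.columns:
        df = df.assign(roi=df["structure"])
    curves = []
    for (pid, structure, roi), grp in df.groupby(
        ["patient_id", "structure", "roi"], sort=True
    ):
        grp = grp.sort_values("time_h")
        try:
            samples = tuple(
                TimeActivitySample(float(r.time_h), float(r.activity_MBq))
                for r in grp.itertuples()
            )
            curves.append(TimeActivityCurve(str(pid), str(structure), samples, roi=str(roi)))
        except ValueError as exc:
            first_line = int(grp.index[0]) + 2  # header + 1-based
            raise SchemaError(f"{path}: near line {first_line}: {exc}") from exc
    return curves


def write_time_activity_csv(curves: Iterable[TimeActivityCurve], path: str | Path) -> None:
    rows = [
        {
            "patient_id": c.patient_id,
            "structure": c.structure,
            "roi": c.roi,
            "time_h": s.time,
            "activity_MBq": s.activity,
        }
        for c in curves
        for s in c.samples
    ]
    pd.DataFrame(rows, columns=["patient_id", "structure", "roi", "time_h", "activity_MBq"]).to_csv(
        path, index=False, float_format="%.10g", lineterminator="\n"
    )


def read_phantom_csv(path: str | Path) -> list[PhantomMeasurement]:
    df = pd.read_csv(path)
    _require_columns(df, _PH_COLUMNS, path)
    out = []
    for r in df.itertuples():
        try:
            out.append(
                PhantomMeasurement(
                    str(r.object_label), float(r.scan_length_min),
                    int(r.repeat_index), float(r.activity_MBq),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: line {r.Index + 2}: {exc}") from exc
    return out


def write_phantom_csv(measurements: Iterable[PhantomMeasurement], path: str | Path) -> None:
    rows = [
        {
            "object_label": m.object_label,
            "scan_length_min": m.scan_length,
            "repeat_index": m.repeat_index,
            "activity_MBq": m.activity,
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=_PH_COLUMNS).to_csv(
        path, index=False, float_format="%.10g", lineterminator="\n"
    )


def write_schedules_csv(schedules: Iterable[SamplingSchedule], path: str | Path) -> None:
    rows = []
    for s in schedules:
        t = list(s.times) + [None] * (3 - len(s.times))
        rows.append({"t1_h": t[0], "t2_h": t[1], "t3_h": t[2]})
    pd.DataFrame(rows, columns=["t1_h", "t2_h", "t3_h"]).to_csv(
        path, index=False, float_format="%.10g", lineterminator="\n"
    )


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_report_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a report table at the fixed 6-significant-digit precision."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


# -- JSON codecs for domain artifacts ---------------------------------------

def write_noise_model(model: NoiseModel, path: str | Path, meta: Mapping | None = None) -> None:
    write_json({**model.to_json(), "meta": dict(meta or {})}, path)


def read_noise_model(path: str | Path) -> NoiseModel:
    return NoiseModel.from_json(read_json(path))


def write_fit_results(fits: Mapping[str, FitResult], path: str | Path,
                      meta: Mapping | None = None) -> None:
    write_json(
        {"fits": {k: f.to_json() for k, f in fits.items()}, "meta": dict(meta or {})}, path
    )


def read_fit_results(path: str | Path) -> dict[str, FitResult]:
    rec = read_json(path)
    return {k: FitResult.from_json(v) for k, v in rec["fits"].items()}


def write_distributions(dists: Mapping[str, CohortDistribution], path: str | Path,
                        meta: Mapping | None = None) -> None:
    write_json(
        {"distributions": {k: d.to_json() for k, d in dists.items()},
         "meta": dict(meta or {})},
        path,
    )


def read_distributions(path: str | Path) -> dict[str, CohortDistribution]:
    rec = read_json(path)
    return {k: CohortDistribution.from_json(v) for k, v in rec["distributions"].items()}
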