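"""Readers, writers, validation and run configuration.

Canonical on-disk format: two CSV files.

* ``long.csv`` -- one row per subject-visit-marker: ``subject_id``, ``time``
  (years since baseline, 0-based continuous), ``marker``, ``marker_value``
  (raw scale, mg/dl semantics), ``log_marker`` (natural log; recomputed if
  absent), plus baseline covariates repeated on each row.
* ``surv.csv`` -- one row per subject: ``subject_id``, ``event_time``
  (years), ``event`` (1 = CVD death, 0 = censored), baseline covariates.

A wide-by-phase importer is provided since cohort extracts often ship one
column per visit phase.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

LONG_REQUIRED = ["subject_id", "time", "marker", "marker_value"]
SURV_REQUIRED = ["subject_id", "event_time", "event"]


@dataclass
class RunConfig:
    markers: list[str] = field(default_factory=lambda: ["TC", "LDL", "HDL"])
    adjustment: list[str] = field(default_factory=lambda: ["diabetes", "smoking", "lipid_drugs", "bmi", "sbp"])
    fraction: float = 0.10
    n_intervals: int = 6
    quad_points: int = 9
    min_events: int = 20
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self):
        if self.fraction <= -1:
            raise ValueError("fraction must be > -1")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing required column(s): {missing}")


def read_cohort(long_path: str | Path, surv_path: str | Path,
                schema: dict[str, str] | None = None, strict: bool = True
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and validate the two cohort tables.

    ``schema`` optionally maps canonical column names to the names used in
    the files. Under ``strict`` the load fails on non-positive marker values
    (they have no logarithm); otherwise offending rows are dropped with a
    report.
    """
    long = pd.read_csv(long_path)
    surv = pd.read_csv(surv_path)
    if schema:
        long = long.rename(columns={v: k for k, v in schema.items()})
        surv = surv.rename(columns={v: k for k, v in schema.items()})
    _require_columns(long, LONG_REQUIRED, "longitudinal")
    _require_columns(surv, SURV_REQUIRED, "survival")

    bad = long.index[~(long["marker_value"] > 0)].tolist()
    if bad:
        msg = f"{len(bad)} longitudinal row(s) with non-positive marker_value (rows {bad[:10]}...)"
        if strict:
            raise ValueError(msg + "; log transform undefined")
        long = long.drop(index=bad)
    if "log_marker" not in long.columns:
        long = long.assign(log_marker=np.log(long["marker_value"]))

    extra = set(long["subject_id"]) - set(surv["subject_id"])
    if extra:
        raise ValueError(f"subjects present in the longitudinal table but not the survival "
                         f"table: {sorted(extra)[:20]}")
    if (surv["event_time"] <= 0).any():
        raise ValueError("event_time must be > 0 for every subject")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    merged = long.merge(surv[["subject_id", "event_time"]], on="subject_id")
    late = merged["time"] > merged["event_time"] + 1e-9
    if late.any():
        raise ValueError(f"{int(late.sum())} longitudinal record(s) postdate the subject's "
                         "event/censoring time")
    return long, surv


def write_cohort(long: pd.DataFrame, surv: pd.DataFrame, out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lp, sp = out / "long.csv", out / "surv.csv"
    long.to_csv(lp, index=False)
    surv.to_csv(sp, index=False)
    return lp, sp


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh)


def wide_to_long(wide: pd.DataFrame, marker: str, phase_columns: list[str],
                 visit_years: list[float], covariates: list[str] | None = None) -> pd.DataFrame:
    """Convert a wide-by-phase extract (one column per visit) to long format.

    Missing cells (NaN) are dropped, matching the convention that a missed
    visit contributes no row.
    """
    if len(phase_columns) != len(visit_years):
        raise ValueError("phase_columns and visit_years must align")
    covariates = covariates or []
    rows = []
    for col, yr in zip(phase_columns, visit_years):
        sub = wide[["subject_id", col] + covariates].rename(columns={col: "marker_value"})
        sub = sub.dropna(subset=["marker_value"])
        sub.insert(1, "time", float(yr))
        sub.insert(2, "marker", marker)
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True).sort_values(["subject_id", "time"], kind="stable")
    out["log_marker"] = np.log(out["marker_value"].to_numpy(float))
    return out.reset_index(drop=True)


def write_manifest(out_dir: str | Path, config: RunConfig | dict, seed: int | None = None) -> Path:
    """Machine-readable record of a run: config, seed and library versions."""
    import lipidjm
    import scipy
    import statsmodels

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config) if not isinstance(config, dict) else config,
        "seed": seed,
        "versions": {
            "lipidjm": getattr(lipidjm, "__version__", "0"),
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    path = out / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
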