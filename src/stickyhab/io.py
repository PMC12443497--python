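"""File formats, run configuration and the end-to-end pipeline.

Formats are deliberately plain:

* stage CSV — columns ``date, level_m`` (daily, no gaps);
* field CSV — columns ``cell_id, area_m2, velocity_ms, depth_m,
  temp_c``, optionally with a leading ``date`` column for a long table
  of several snapshots;
* frequency-table CSV — ``depth_lo_m, depth_hi_m, count``;
* curves — JSON (deterministic key order, bit-exact round-trip);
* outputs — per-cell suitability CSV, summary CSV, and a run-metadata
  JSON carrying the mode, seed, input hashes and package version.

Readers validate and reject; they never coerce malformed values or let
NaN propagate silently.  Writers use fixed six-significant-digit float
formatting so outputs are deterministic across platforms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import DepthFrequencyTable, SuitabilityCurve
from .drawdown import StageSeries, si_l_series
from .habitat import FIELD_COLUMNS, HabitatSummary, HydroField, cell_suitabilities, summarize

__all__ = [
    "read_stage_csv",
    "write_stage_csv",
    "read_field_csv",
    "read_frequency_csv",
    "read_curve_json",
    "write_curve_json",
    "write_suitability_csv",
    "write_summary",
    "RunConfig",
    "run_pipeline",
]

FLOAT_FMT = "%.6g"


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0])
        raise ValueError(f"{path}: non-numeric value in column {col!r} (row {row})")
    return vals


def read_stage_csv(path) -> StageSeries:
    """Read and validate a daily stage series (``date, level_m``)."""
    df = pd.read_csv(path)
    _require_columns(df, ["date", "level_m"], path)
    try:
        dates = pd.DatetimeIndex(pd.to_datetime(df["date"], format="ISO8601"))
    except (ValueError, TypeError) as e:
        raise ValueError(f"{path}: unparseable date: {e}") from None
    levels = _numeric(df, "level_m", path).to_numpy(float)
    return StageSeries(dates=dates, levels=levels)  # gap/duplicate checks inside


def write_stage_csv(series: StageSeries, path) -> None:
    df = pd.DataFrame(
        {"date": [str(d.date()) for d in series.dates], "level_m": series.levels}
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_field_csv(path, date=None):
    """Read per-cell hydraulics.

    Without a ``date`` column the file is one snapshot and ``date``
    must be supplied.  With a ``date`` column, returns a dict
    ``{Timestamp: HydroField}``.
    """
    df = pd.read_csv(path, dtype={"cell_id": str})
    if "date" in df.columns:
        _require_columns(df, FIELD_COLUMNS, path)
        for col in FIELD_COLUMNS[1:]:
            df[col] = _numeric(df, col, path)
        out = {}
        for d, grp in df.groupby("date"):
            out[pd.Timestamp(d)] = HydroField(
                date=d, cells=grp[FIELD_COLUMNS].reset_index(drop=True)
            )
        return out
    if date is None:
        raise ValueError(f"{path}: no date column; pass the snapshot date explicitly")
    _require_columns(df, FIELD_COLUMNS, path)
    for col in FIELD_COLUMNS[1:]:
        df[col] = _numeric(df, col, path)
    return HydroField(date=date, cells=df[FIELD_COLUMNS])


def read_frequency_csv(path) -> DepthFrequencyTable:
    """Read an egg-depth frequency table (``depth_lo_m, depth_hi_m, count``)."""
    df = pd.read_csv(path)
    _require_columns(df, ["depth_lo_m", "depth_hi_m", "count"], path)
    lo = _numeric(df, "depth_lo_m", path)
    hi = _numeric(df, "depth_hi_m", path)
    counts = _numeric(df, "count", path)
    if not np.allclose(counts, counts.round()):
        raise ValueError(f"{path}: counts must be integers")
    return DepthFrequencyTable(
        bins=tuple(zip(lo, hi)), counts=tuple(int(c) for c in counts)
    )


def read_curve_json(path) -> SuitabilityCurve:
    return SuitabilityCurve.from_json(Path(path).read_text())


def write_curve_json(curve: SuitabilityCurve, path) -> None:
    Path(path).write_text(curve.to_json())


def write_suitability_csv(suit: pd.DataFrame, path) -> None:
    suit.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_summary(summaries: list[HabitatSummary], path) -> None:
    """Write the per-date habitat summary table as CSV."""
    rows = [s.to_row() for s in summaries]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    stage_csv: str
    field_csv: str
    out_dir: str
    velocity_curve: Optional[str] = None  # JSON path; packaged default if None
    depth_curve: Optional[str] = None
    temperature_curve: Optional[str] = None
    frequency_csv: Optional[str] = None  # packaged egg-depth table if None
    mode: str = "geometric_mean"
    window_days: int = 5
    date_from: Optional[str] = None
    date_to: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("geometric_mean", "product"):
            raise ValueError(f"mode must be geometric_mean or product, got {self.mode!r}")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _load_curves(config: RunConfig) -> dict:
    from . import datasets
    from .curves import make_drawdown_curve

    curves = datasets.default_curves()
    for key, attr in (
        ("velocity", "velocity_curve"),
        ("depth", "depth_curve"),
        ("temperature", "temperature_curve"),
    ):
        p = getattr(config, attr)
        if p is not None:
            curves[key] = read_curve_json(p)
    if config.frequency_csv is not None:
        curves["drawdown"] = make_drawdown_curve(read_frequency_csv(config.frequency_csv))
    return curves


def run_pipeline(config: RunConfig) -> dict:
    """Execute curves → drawdown → habitat → summaries.

    Writes a per-cell suitability CSV per date, one summary CSV and a
    run-metadata JSON into ``config.out_dir``; returns paths plus the
    in-memory summary list.  Deterministic for fixed inputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    curves = _stage("curves", _load_curves, config)
    stage = _stage("stage-input", read_stage_csv, config.stage_csv)
    if config.date_from or config.date_to:
        stage = stage.slice(
            config.date_from or stage.dates[0], config.date_to or stage.dates[-1]
        )
    dd = _stage(
        "drawdown", si_l_series, stage, curves["drawdown"], window_days=config.window_days
    )
    fields = _stage("field-input", read_field_csv, config.field_csv)
    if isinstance(fields, HydroField):
        fields = {fields.date: fields}

    si_l_by_date = {
        d: float(s) for d, s in zip(dd.dates, dd.si_l) if pd.Timestamp(d) in fields
    }
    hydraulic = {k: curves[k] for k in ("velocity", "depth", "temperature")}
    missing = [str(pd.Timestamp(d).date()) for d in fields if d not in si_l_by_date]
    if missing:
        raise RuntimeError(
            f"pipeline stage 'habitat' failed: field dates without a defined "
            f"SI_L value: {missing[:5]}"
        )
    summaries = _stage("habitat", summarize, fields, hydraulic, si_l_by_date, config.mode)

    cell_paths = []
    for d in sorted(fields):
        suit = cell_suitabilities(fields[d], hydraulic, si_l_by_date[d], mode=config.mode)
        p = out_dir / f"cells_{pd.Timestamp(d).date()}.csv"
        write_suitability_csv(suit, p)
        cell_paths.append(str(p))
    summary_path = out_dir / "summary.csv"
    write_summary(summaries, summary_path)

    meta = {
        "package": "stickyhab",
        "version": __version__,
        "mode": config.mode,
        "window_days": config.window_days,
        "seed": config.seed,
        "inputs": {
            "stage_csv": {"path": str(config.stage_csv), "sha256": _sha256(config.stage_csv)},
            "field_csv": {"path": str(config.field_csv), "sha256": _sha256(config.field_csv)},
        },
        "n_dates": len(summaries),
    }
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, sort_keys=True, indent=2))
    return {
        "summaries": summaries,
        "summary_csv": str(summary_path),
        "cell_csvs": cell_paths,
        "metadata_json": str(meta_path),
    }
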