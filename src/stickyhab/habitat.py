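"""Per-cell habitat suitability and weighted usable area.

Each computational cell of a 2-D hydrodynamic snapshot carries an area
A_i plus depth-averaged velocity, depth and temperature.  Factor
suitabilities SI_V, SI_H, SI_T come from the hydraulic curves; the
water-level-fluctuation index SI_L is a single scalar per date (one
stage gauge) applied uniformly to all cells.  The two life-stage
composites are

    spawning:  HSI_i = f(SI_V, SI_H, SI_T)
    hatching:  HSI_i = f(SI_V, SI_H, SI_T, SI_L)

where ``f`` is either the geometric mean of the factors (default) or
their plain product — the mode is a run-level switch recorded in every
output.  Either way a zero factor annihilates the composite.  The
weighted usable area is WUA = Σ A_i × HSI_i, and cells are classed into
five suitability bands (very_low .. very_high) on 0.2-wide HSI bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .curves import SuitabilityCurve, evaluate

__all__ = [
    "CLASS_LABELS",
    "HydroCell",
    "HydroField",
    "HabitatSummary",
    "cell_suitabilities",
    "spawning_hsi",
    "hatching_hsi",
    "classify_hsi",
    "weighted_usable_area",
    "class_area_table",
    "summarize",
]

CLASS_LABELS = ("very_low", "low", "medium", "high", "very_high")
_CLASS_EDGES = np.array([0.2, 0.4, 0.6, 0.8])
MODES = ("geometric_mean", "product")

FIELD_COLUMNS = ["cell_id", "area_m2", "velocity_ms", "depth_m", "temp_c"]


@dataclass(frozen=True)
class HydroCell:
    """One computational unit of the hydrodynamic mesh."""

    cell_id: str
    area: float  # m^2
    velocity: float  # m/s
    depth: float  # m
    temperature: float  # degC

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError(f"cell {self.cell_id}: area must be positive")
        if self.velocity < 0:
            raise ValueError(f"cell {self.cell_id}: velocity must be >= 0")
        if self.depth < 0:
            raise ValueError(f"cell {self.cell_id}: depth must be >= 0")


@dataclass(frozen=True)
class HydroField:
    """A dated snapshot of per-cell hydraulics, DataFrame-backed.

    Columns: ``cell_id, area_m2, velocity_ms, depth_m, temp_c``.
    """

    date: pd.Timestamp
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "date", pd.Timestamp(self.date))
        df = self.cells
        missing = [c for c in FIELD_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"field is missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("field has no cells")
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
            raise ValueError(f"duplicate cell ids: {dup[:5]}")
        for col in FIELD_COLUMNS[1:]:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                bad = df.loc[vals.isna(), "cell_id"].iloc[0]
                raise ValueError(f"non-numeric {col} in cell {bad}")
        bad_area = df.loc[df["area_m2"] <= 0, "cell_id"]
        if len(bad_area):
            raise ValueError(f"non-positive area in cell {bad_area.iloc[0]}")
        if (df["velocity_ms"] < 0).any() or (df["depth_m"] < 0).any():
            raise ValueError("velocity and depth must be non-negative")
        object.__setattr__(self, "cells", df.reset_index(drop=True))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total_area(self) -> float:
        return float(self.cells["area_m2"].sum())

    @classmethod
    def from_cells(cls, date, cells: Iterable[HydroCell]) -> "HydroField":
        rows = [
            (c.cell_id, c.area, c.velocity, c.depth, c.temperature) for c in cells
        ]
        return cls(date, pd.DataFrame(rows, columns=FIELD_COLUMNS))


def _check_unit(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"{name} values must lie in [0, 1]")
    return arr


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def spawning_hsi(si_v, si_h, si_t, mode: str = "geometric_mean"):
    """Spawning-stage composite of the three hydraulic suitabilities."""
    _check_mode(mode)
    v = _check_unit(si_v, "si_v")
    h = _check_unit(si_h, "si_h")
    t = _check_unit(si_t, "si_t")
    prod = v * h * t
    out = np.cbrt(prod) if mode == "geometric_mean" else prod
    return float(out) if np.ndim(out) == 0 else out


def hatching_hsi(si_v, si_h, si_t, si_l, mode: str = "geometric_mean"):
    """Hatching-stage composite: hydraulic suitabilities times SI_L."""
    _check_mode(mode)
    v = _check_unit(si_v, "si_v")
    h = _check_unit(si_h, "si_h")
    t = _check_unit(si_t, "si_t")
    l = _check_unit(si_l, "si_l")
    prod = v * h * t * l
    out = prod ** 0.25 if mode == "geometric_mean" else prod
    return float(out) if np.ndim(out) == 0 else out


def classify_hsi(hsi):
    """Map HSI to the five suitability classes.

    Bins are half-open on the left — [0, 0.2) very_low, [0.2, 0.4) low,
    [0.4, 0.6) medium, [0.6, 0.8) high — with a closed top bin
    [0.8, 1.0] very_high, so boundary values go to the upper class.
    """
    arr = _check_unit(hsi, "hsi")
    idx = np.digitize(arr, _CLASS_EDGES, right=False)
    labels = np.take(CLASS_LABELS, idx)
    return str(labels) if np.ndim(arr) == 0 else labels


def cell_suitabilities(
    field: HydroField,
    curves: Mapping[str, SuitabilityCurve],
    si_l: float,
    mode: str = "geometric_mean",
) -> pd.DataFrame:
    """Per-cell factor suitabilities, composites and classes.

    ``curves`` must provide ``velocity``, ``depth`` and ``temperature``;
    ``si_l`` (scalar in [0, 1]) applies uniformly to every cell.
    """
    _check_mode(mode)
    for key in ("velocity", "depth", "temperature"):
        if key not in curves:
            raise ValueError(f"missing suitability curve: {key!r}")
    if not np.isfinite(si_l) or not 0.0 <= si_l <= 1.0:
        raise ValueError(f"si_l must lie in [0, 1], got {si_l}")
    df = field.cells
    out = pd.DataFrame({"cell_id": df["cell_id"], "area_m2": df["area_m2"]})
    out["si_v"] = evaluate(curves["velocity"], df["velocity_ms"].to_numpy())
    out["si_h"] = evaluate(curves["depth"], df["depth_m"].to_numpy())
    out["si_t"] = evaluate(curves["temperature"], df["temp_c"].to_numpy())
    out["si_l"] = float(si_l)
    out["hsi_spawn"] = spawning_hsi(out["si_v"], out["si_h"], out["si_t"], mode=mode)
    out["hsi_hatch"] = hatching_hsi(
        out["si_v"], out["si_h"], out["si_t"], out["si_l"], mode=mode
    )
    out["class_spawn"] = classify_hsi(out["hsi_spawn"])
    out["class_hatch"] = classify_hsi(out["hsi_hatch"])
    out.attrs["mode"] = mode
    out.attrs["date"] = str(field.date.date())
    return out


def weighted_usable_area(areas, hsi) -> float:
    """WUA = Σ A_i × HSI_i (m²)."""
    a = np.asarray(areas, dtype=float)
    h = _check_unit(hsi, "hsi")
    if a.size == 0:
        raise ValueError("empty cell collection")
    if a.shape != h.shape:
        raise ValueError("areas and hsi must align")
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    return float(np.sum(a * h))


def class_area_table(suit: pd.DataFrame) -> pd.DataFrame:
    """Area fraction per suitability class for both life stages.

    Rows are the five classes in order; columns ``spawning`` and
    ``hatching`` are area fractions (each summing to 1), and
    ``change_pct`` is 100 × (hatching − spawning) / spawning, NaN where
    the spawning fraction is zero.
    """
    if len(suit) == 0:
        raise ValueError("empty suitability table")
    total = suit["area_m2"].sum()
    frac = {}
    for stage, col in (("spawning", "class_spawn"), ("hatching", "class_hatch")):
        by = suit.groupby(col)["area_m2"].sum()
        frac[stage] = np.array([by.get(c, 0.0) for c in CLASS_LABELS]) / total
    tab = pd.DataFrame(frac, index=pd.Index(CLASS_LABELS, name="class"))
    with np.errstate(divide="ignore", invalid="ignore"):
        change = 100.0 * (tab["hatching"] - tab["spawning"]) / tab["spawning"]
    tab["change_pct"] = change.where(tab["spawning"] > 0)
    return tab


@dataclass(frozen=True)
class HabitatSummary:
    """One date's habitat roll-up."""

    date: pd.Timestamp
    wua_spawn: float  # m^2
    wua_hatch: float  # m^2
    wua_reduction_pct: Optional[float]
    class_fractions: pd.DataFrame = field(compare=False, repr=False, default=None)
    mode: str = "geometric_mean"

    def to_row(self) -> dict:
        row = {
            "date": str(pd.Timestamp(self.date).date()),
            "wua_spawn_m2": self.wua_spawn,
            "wua_hatch_m2": self.wua_hatch,
            "wua_reduction_pct": self.wua_reduction_pct,
            "mode": self.mode,
        }
        if self.class_fractions is not None:
            for stage in ("spawning", "hatching"):
                for cls in CLASS_LABELS:
                    row[f"frac_{stage}_{cls}"] = self.class_fractions.loc[cls, stage]
        return row


def summarize(
    fields: Mapping,
    curves: Mapping[str, SuitabilityCurve],
    si_l_by_date: Mapping,
    mode: str = "geometric_mean",
) -> list[HabitatSummary]:
    """Per-date habitat summaries for aligned fields and SI_L values.

    ``fields`` maps date -> HydroField and ``si_l_by_date`` maps
    date -> scalar SI_L; the date sets must match exactly.
    """
    f_dates = {pd.Timestamp(d) for d in fields}
    s_dates = {pd.Timestamp(d) for d in si_l_by_date}
    if f_dates != s_dates:
        only_f = sorted(str(d.date()) for d in f_dates - s_dates)
        only_s = sorted(str(d.date()) for d in s_dates - f_dates)
        raise ValueError(
            f"field/SI_L date misalignment: fields-only {only_f[:5]}, "
            f"si_l-only {only_s[:5]}"
        )
    si_l_norm = {pd.Timestamp(d): v for d, v in si_l_by_date.items()}
    out = []
    for d in sorted(f_dates):
        field_d = fields[[k for k in fields if pd.Timestamp(k) == d][0]]
        suit = cell_suitabilities(field_d, curves, si_l_norm[d], mode=mode)
        wua_s = weighted_usable_area(suit["area_m2"], suit["hsi_spawn"])
        wua_h = weighted_usable_area(suit["area_m2"], suit["hsi_hatch"])
        red = 100.0 * (wua_s - wua_h) / wua_s if wua_s > 0 else None
        out.append(
            HabitatSummary(
                date=d,
                wua_spawn=wua_s,
                wua_hatch=wua_h,
                wua_reduction_pct=red,
                class_fractions=class_area_table(suit),
                mode=mode,
            )
        )
    return out
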