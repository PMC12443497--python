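"""Water-level drawdown analysis.

Adhesive fish eggs need roughly five stable days from deposition to the
larvae's free-swimming stage (about two days to hatch plus three to
four days post-hatch).  An egg stranded by a receding waterline at any
point in that window desiccates, so the biologically relevant quantity
on a spawning day ``t`` is the *forward-looking cumulative drop*

    D(t) = max(0, level(t) − min_{k=1..w} level(t + k)),   w = 5 days.

The intermediate minimum governs: a level that dips and recovers still
kills the eggs it exposed.  For a monotone decline this coincides with
the simpler endpoint difference ``level(t) − level(t + w)``, which is
available behind the ``endpoint_only`` switch for sensitivity analysis.

``SI_L(t)`` is the drawdown suitability curve evaluated at ``D(t)`` —
the fraction of a depth-distributed egg cohort spawned on day ``t``
that is not stranded during the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .curves import FIVE_DAY_DROP, SuitabilityCurve, evaluate

__all__ = [
    "StageSeries",
    "DrawdownSeries",
    "five_day_drop",
    "si_l_series",
    "period_mean_si_l",
    "max_sustainable_daily_decline",
    "decline_stats",
]


@dataclass(frozen=True)
class StageSeries:
    """Daily water levels at a gauge.

    ``dates`` must be consecutive calendar days (no gaps — fill or
    reject upstream); ``levels`` are finite water levels in metres.
    """

    dates: pd.DatetimeIndex
    levels: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "levels", levels)
        if len(dates) != len(levels):
            raise ValueError("dates and levels must have equal length")
        if len(dates) == 0:
            raise ValueError("stage series is empty")
        if dates.has_duplicates:
            dup = dates[dates.duplicated()].unique()
            raise ValueError(f"duplicate dates: {[str(d.date()) for d in dup]}")
        if len(dates) > 1:
            steps = np.diff(dates.values).astype("timedelta64[D]")
            if np.any(steps != np.timedelta64(1, "D")):
                missing = pd.date_range(dates[0], dates[-1], freq="D").difference(dates)
                raise ValueError(
                    "stage series has calendar gaps; missing dates: "
                    + ", ".join(str(d.date()) for d in missing[:10])
                )
        if not np.all(np.isfinite(levels)):
            raise ValueError("levels must be finite")

    def __len__(self) -> int:
        return len(self.dates)

    def to_series(self) -> pd.Series:
        return pd.Series(self.levels, index=self.dates, name="level_m")

    def slice(self, start, end) -> "StageSeries":
        mask = (self.dates >= pd.Timestamp(start)) & (self.dates <= pd.Timestamp(end))
        return StageSeries(self.dates[mask], self.levels[mask])


@dataclass(frozen=True)
class DrawdownSeries:
    """Per-day cumulative drop D(t) and, optionally, SI_L(t).

    Defined only for days with a full forward window; trailing days are
    dropped, never padded.
    """

    dates: pd.DatetimeIndex
    drop: np.ndarray
    si_l: Optional[np.ndarray] = None
    window_days: int = 5

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        drop = np.asarray(self.drop, dtype=float)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "drop", drop)
        if len(dates) != len(drop):
            raise ValueError("dates and drop must have equal length")
        if np.any(drop < 0):
            raise ValueError("drops must be non-negative")
        if self.si_l is not None:
            si_l = np.asarray(self.si_l, dtype=float)
            object.__setattr__(self, "si_l", si_l)
            if len(si_l) != len(dates):
                raise ValueError("si_l length mismatch")
            if np.any((si_l < 0) | (si_l > 1)):
                raise ValueError("si_l values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        data = {"drop_5d_m": self.drop}
        if self.si_l is not None:
            data["si_l"] = self.si_l
        return pd.DataFrame(data, index=self.dates.rename("date"))


def five_day_drop(
    series: StageSeries, window_days: int = 5, endpoint_only: bool = False
) -> DrawdownSeries:
    """Cumulative water-level drop over the forward window.

    ``D(t) = max(0, level(t) − min(level(t+1..t+w)))`` (default), or
    ``max(0, level(t) − level(t+w))`` with ``endpoint_only=True``.
    The last ``window_days`` dates carry no value.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    n = len(series)
    if n <= window_days:
        raise ValueError(
            f"stage series has {n} days; need more than window_days={window_days}"
        )
    levels = series.levels
    if endpoint_only:
        future = levels[window_days:]
    else:
        windows = np.lib.stride_tricks.sliding_window_view(levels[1:], window_days)
        future = windows.min(axis=1)
    drop = np.maximum(0.0, levels[: n - window_days] - future)
    return DrawdownSeries(
        dates=series.dates[: n - window_days], drop=drop, window_days=window_days
    )


def si_l_series(
    series: StageSeries,
    curve: SuitabilityCurve,
    window_days: int = 5,
    endpoint_only: bool = False,
) -> DrawdownSeries:
    """SI_L(t) = drawdown curve evaluated at D(t), for every defined day."""
    if curve.variable != FIVE_DAY_DROP:
        raise ValueError(
            f"expected a drawdown curve (variable '{FIVE_DAY_DROP}'), "
            f"got '{curve.variable}'"
        )
    dd = five_day_drop(series, window_days=window_days, endpoint_only=endpoint_only)
    return DrawdownSeries(
        dates=dd.dates,
        drop=dd.drop,
        si_l=evaluate(curve, dd.drop),
        window_days=window_days,
    )


def period_mean_si_l(dd: DrawdownSeries, start, end) -> float:
    """Arithmetic mean SI_L over the defined days in [start, end]."""
    if dd.si_l is None:
        raise ValueError("DrawdownSeries carries no SI_L values; use si_l_series first")
    mask = (dd.dates >= pd.Timestamp(start)) & (dd.dates <= pd.Timestamp(end))
    if not mask.any():
        raise ValueError(f"no defined SI_L days in [{start}, {end}]")
    return float(np.mean(dd.si_l[mask]))


def max_sustainable_daily_decline(
    curve: SuitabilityCurve, window_days: int = 5
) -> float:
    """Largest constant daily decline whose cumulative window drop stays at
    the drawdown curve's zero point: ``d0 / window_days``, where ``d0`` is
    the smallest drop with SI_L(d0) = 0.

    For the carp/crucian-carp egg-depth table (no eggs deeper than
    0.8 m) and a 5-day window this is 0.8 / 5 = 0.16 m/day — the
    ecological regulation threshold.
    """
    if curve.variable != FIVE_DAY_DROP:
        raise ValueError("expected a drawdown curve")
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    zero = np.flatnonzero(curve.s == 0.0)
    if zero.size == 0:
        raise ValueError("drawdown curve never reaches 0; no sustainable-rate bound")
    d0 = float(curve.x[zero[0]])
    return d0 / window_days


def decline_stats(series: StageSeries, start=None, end=None) -> dict:
    """Regime statistics of daily level changes over [start, end].

    Returns ``mean_daily_change`` (m/day, negative = decline) and
    ``max_daily_drop`` (the most negative single-day change).
    """
    sub = series
    if start is not None or end is not None:
        sub = series.slice(
            start if start is not None else series.dates[0],
            end if end is not None else series.dates[-1],
        )
    if len(sub) < 2:
        raise ValueError("need at least 2 days to compute decline statistics")
    diffs = np.diff(sub.levels)
    return {
        "mean_daily_change": float(np.mean(diffs)),
        "max_daily_drop": float(np.min(diffs)),
        "n_days": int(len(sub)),
    }
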