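"""Validation diagnostics for the drawdown suitability index.

Two independent checks that SI_L behaves as a hatching-success index:

* :func:`lagged_pearson` — larvae counted on day ``t`` were spawned
  about five days earlier, so observed larvae density should correlate
  with SI_L shifted earlier by the egg-to-free-swimming lag.
* :func:`cohort_survival` — a Monte-Carlo oracle: place a sampled egg
  cohort at its deposition depths on the spawn date and count the
  fraction whose depth below the initial water surface exceeds the
  realized window drop.  Stranding is a sharp threshold — an egg dies
  exactly when the waterline falls below its depth — so the expected
  surviving fraction equals the drawdown curve at the realized drop.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .drawdown import DrawdownSeries, StageSeries, five_day_drop

__all__ = ["lagged_pearson", "cohort_survival"]


def lagged_pearson(
    si_l: DrawdownSeries, density: pd.Series, lag_days: int = 5
) -> dict:
    """Pearson correlation between larvae density and lagged SI_L.

    Pairs ``density(t)`` with ``SI_L(t − lag_days)``; returns
    ``{"r": ..., "n": ..., "p": ...}`` with a two-sided p-value from
    the standard t transform.
    """
    if si_l.si_l is None:
        raise ValueError("DrawdownSeries carries no SI_L values")
    if lag_days < 0:
        raise ValueError("lag_days must be >= 0")
    shifted = pd.Series(
        si_l.si_l, index=si_l.dates + pd.Timedelta(days=lag_days)
    )
    joined = pd.concat(
        {"si_l": shifted, "density": pd.Series(density)}, axis=1, join="inner"
    ).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"only {n} paired days after applying the lag; need >= 3")
    x = joined["si_l"].to_numpy(float)
    y = joined["density"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: an input series is constant")
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "n": n, "p": float(res.pvalue)}


def cohort_survival(
    stage: StageSeries,
    egg_depths,
    spawn_date,
    window_days: int = 5,
    endpoint_only: bool = False,
) -> float:
    """Surviving fraction of an egg cohort spawned on ``spawn_date``.

    An egg deposited ``depth`` metres below the spawn-day water surface
    survives the incubation window iff ``depth > D(spawn_date)``, the
    realized cumulative drop.
    """
    depths = np.asarray(egg_depths, dtype=float)
    if depths.size == 0:
        raise ValueError("empty egg cohort")
    if np.any(depths < 0) or not np.all(np.isfinite(depths)):
        raise ValueError("egg depths must be finite and non-negative")
    dd = five_day_drop(stage, window_days=window_days, endpoint_only=endpoint_only)
    ts = pd.Timestamp(spawn_date)
    pos = dd.dates.get_indexer([ts])
    if pos[0] < 0:
        raise ValueError(
            f"spawn date {ts.date()} has no full {window_days}-day window "
            "within the stage series"
        )
    drop = dd.drop[pos[0]]
    return float(np.mean(depths > drop))
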