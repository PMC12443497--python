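"""Synthetic inputs with the statistical structure of a regulated
reservoir tributary.

These generators stand in for a hydrodynamic model and gauge record so
the whole pipeline runs and is testable without external data:

* :func:`gen_stage_series` — daily stage hydrographs under a pre-dam
  regime (stable level, occasional rainfall pulses that recede over the
  following days) or a post-dam drawdown regime (sustained spring
  decline: mean −0.22 m/day in April, −0.32 m/day in May, single-day
  drops bounded at −0.61 m).  Daily changes are truncated-normal around
  the monthly mean — the minimal distribution consistent with a stated
  mean and extreme.
* :func:`gen_hydro_field` — an unstructured-mesh-like snapshot of cell
  area / velocity / depth / temperature on a longitudinal (upstream →
  downstream) gradient with a cross-channel velocity core:
  velocities 0–1.4 m/s (≈0.3 m/s mid-channel, < 0.2 m/s at the
  margins), depths 0–14.5 m deepening downstream, temperatures cooling
  downstream (means 22.9 → 20.6 °C).
* :func:`gen_egg_depths` — egg deposition depths drawn
  bin-proportionally from a depth-frequency table.
* :func:`gen_larvae_density` — daily larvae density proportional to
  SI_L lagged by the egg-to-free-swimming window, with multiplicative
  log-normal observation noise.

All draws flow from one seeded NumPy generator per call: identical
spec + seed reproduces identical output bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .curves import DepthFrequencyTable
from .drawdown import DrawdownSeries, StageSeries
from .habitat import FIELD_COLUMNS, HydroField

__all__ = [
    "RegimeSpec",
    "FieldSpec",
    "gen_stage_series",
    "gen_hydro_field",
    "gen_egg_depths",
    "gen_larvae_density",
]


@dataclass(frozen=True)
class RegimeSpec:
    """Parameters of a stage regime.

    ``monthly_mean_change`` maps calendar month -> mean daily level
    change (m/day); months not listed fall back to ``default_change``.
    ``daily_spread`` is the standard deviation of the daily change
    before truncation at ``max_daily_drop`` (and at 0 from above for
    the post-dam drawdown, which never rises).  Rainfall pulses apply
    to the pre-dam regime only.
    """

    regime: str = "post_dam"
    monthly_mean_change: Mapping[int, float] = field(
        default_factory=lambda: {4: -0.22, 5: -0.32}
    )
    default_change: float = 0.0
    daily_spread: float = 0.08
    max_daily_drop: float = -0.61
    pulse_prob: float = 0.0
    pulse_magnitude: float = 0.4  # mean rainfall rise, m
    pulse_decay: float = 0.35  # fraction of pulse excess shed per day
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("pre_dam", "post_dam"):
            raise ValueError("regime must be 'pre_dam' or 'post_dam'")
        if self.daily_spread < 0 or not 0 <= self.pulse_prob <= 1:
            raise ValueError("invalid spread or pulse probability")
        if self.max_daily_drop >= 0:
            raise ValueError("max_daily_drop must be negative")

    @classmethod
    def post_dam(cls, seed: int = 0, **kw) -> "RegimeSpec":
        """Spring drawdown regime of the regulated reservoir."""
        defaults = dict(regime="post_dam", default_change=-0.22, seed=seed)
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def pre_dam(cls, seed: int = 0, **kw) -> "RegimeSpec":
        """Near-stable natural regime with occasional rainfall pulses."""
        defaults = dict(
            regime="pre_dam",
            monthly_mean_change={},
            default_change=0.0,
            daily_spread=0.05,
            pulse_prob=0.10,
            seed=seed,
        )
        defaults.update(kw)
        return cls(**defaults)

    def mean_change(self, month: int) -> float:
        return float(self.monthly_mean_change.get(month, self.default_change))


def _truncated_daily_changes(rng, means, spread, lo, hi):
    """Daily changes ~ Normal(mean, spread) truncated to [lo, hi]."""
    means = np.asarray(means, dtype=float)
    if spread == 0.0:
        return np.clip(means, lo, hi)
    a = (lo - means) / spread
    b = (hi - means) / spread
    return stats.truncnorm.rvs(
        a, b, loc=means, scale=spread, size=means.shape, random_state=rng
    )


def gen_stage_series(
    spec: RegimeSpec, start, end, start_level: float = 165.0
) -> StageSeries:
    """Generate a daily stage series over [start, end] inclusive."""
    dates = pd.date_range(start, end, freq="D")
    if len(dates) < 2:
        raise ValueError(f"date range [{start}, {end}] is too short")
    rng = np.random.default_rng(spec.seed)
    n = len(dates)
    levels = np.empty(n)
    levels[0] = start_level
    if spec.regime == "post_dam":
        means = np.array([spec.mean_change(d.month) for d in dates[1:]])
        # drawdown never raises the level: truncate at 0 from above
        changes = _truncated_daily_changes(
            rng, means, spec.daily_spread, spec.max_daily_drop, 0.0
        )
        levels[1:] = start_level + np.cumsum(changes)
    else:
        baseline = start_level
        for i in range(1, n):
            mean = spec.mean_change(dates[i].month)
            change = _truncated_daily_changes(
                rng, [mean], spec.daily_spread, spec.max_daily_drop, np.inf
            )[0]
            # rainfall pulse: sudden rise that recedes over following days
            if spec.pulse_prob > 0 and rng.random() < spec.pulse_prob:
                change += rng.exponential(spec.pulse_magnitude)
            excess = levels[i - 1] - baseline
            levels[i] = levels[i - 1] + change - spec.pulse_decay * excess
    return StageSeries(dates=dates, levels=levels)


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of a synthetic 2-D hydro snapshot.

    Cells get a longitudinal coordinate x ∈ [0, 1] (0 = upstream) and a
    cross-channel coordinate y ∈ [−1, 1] (0 = mid-channel); depth grows
    downstream and toward mid-channel, velocity peaks mid-channel,
    temperature cools downstream.
    """

    n_cells: int = 2000
    velocity_range: tuple[float, float] = (0.0, 1.4)
    depth_range: tuple[float, float] = (0.0, 14.5)
    core_velocity: float = 0.3  # mid-channel typical speed, m/s
    temp_upstream_mean: float = 22.9  # degC
    temp_downstream_mean: float = 20.6  # degC
    temp_spread: float = 1.5
    temp_range: tuple[float, float] = (13.7, 29.2)
    mean_cell_area: float = 100.0  # m^2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for lo, hi in (self.velocity_range, self.depth_range, self.temp_range):
            if not lo < hi:
                raise ValueError("ranges must satisfy lo < hi")
        if self.mean_cell_area <= 0:
            raise ValueError("mean_cell_area must be positive")


def gen_hydro_field(spec: FieldSpec, date) -> HydroField:
    """Generate one dated per-cell hydraulic snapshot."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    x = rng.uniform(0.0, 1.0, n)  # longitudinal, 0 = upstream
    y = rng.uniform(-1.0, 1.0, n)  # cross-channel, 0 = centre

    v_lo, v_hi = spec.velocity_range
    d_lo, d_hi = spec.depth_range
    t_lo, t_hi = spec.temp_range

    depth = d_hi * (x ** 0.8) * (1.0 - 0.6 * y ** 2) + rng.normal(0.0, 0.15, n)
    depth = np.clip(depth, d_lo, d_hi)

    # cross-channel velocity core; a skewed tail of constricted fast reaches
    cross = np.exp(-((y / 0.5) ** 2))
    speed_scale = spec.core_velocity + (v_hi - spec.core_velocity) * rng.random(n) ** 4
    velocity = speed_scale * cross + rng.normal(0.0, 0.02, n)
    velocity = np.clip(velocity, v_lo, v_hi)

    temp = (
        spec.temp_upstream_mean
        + (spec.temp_downstream_mean - spec.temp_upstream_mean) * x
        + rng.normal(0.0, spec.temp_spread, n)
    )
    temp = np.clip(temp, t_lo, t_hi)

    area = rng.lognormal(np.log(spec.mean_cell_area), 0.3, n)

    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(n)],
            "area_m2": area,
            "velocity_ms": velocity,
            "depth_m": depth,
            "temp_c": temp,
        },
        columns=FIELD_COLUMNS,
    )
    return HydroField(date=date, cells=cells)


def gen_egg_depths(
    n: int, table: DepthFrequencyTable, seed: int = 0
) -> np.ndarray:
    """Sample egg deposition depths bin-proportionally from ``table``,
    uniform within each bin."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table.bins), size=n, p=table.fractions())
    lo = np.array([b[0] for b in table.bins])[idx]
    hi = np.array([b[1] for b in table.bins])[idx]
    return rng.uniform(lo, hi)


def gen_larvae_density(
    si_l: DrawdownSeries,
    lag_days: int = 5,
    noise: float = 0.7,
    seed: int = 0,
    scale: float = 100.0,
) -> pd.Series:
    """Daily larvae density proportional to lagged SI_L.

    ``density(t) = scale × SI_L(t − lag_days) × exp(N(0, noise²))`` —
    larvae counted on day ``t`` hatched from eggs spawned ``lag_days``
    earlier, under multiplicative log-normal sampling noise.  A
    constant SI_L series is flagged with a warning: the downstream
    lagged correlation is then undefined.
    """
    if si_l.si_l is None:
        raise ValueError("DrawdownSeries carries no SI_L values")
    if len(si_l) == 0:
        raise ValueError("empty SI_L series")
    if lag_days < 0:
        raise ValueError("lag_days must be >= 0")
    if np.ptp(si_l.si_l) == 0:
        warnings.warn(
            "SI_L series is constant; lagged correlation against the "
            "generated densities is undefined",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    factor = np.exp(rng.normal(0.0, noise, len(si_l))) if noise > 0 else 1.0
    dens = scale * si_l.si_l * factor
    dates = si_l.dates + pd.Timedelta(days=lag_days)
    return pd.Series(dens, index=dates.rename("date"), name="larvae_density")
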