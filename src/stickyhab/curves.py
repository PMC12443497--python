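"""Piecewise-linear habitat suitability curves.

A habitat suitability curve (HSC) maps one environmental variable —
flow velocity (m/s), water depth (m), water temperature (°C), or the
cumulative 5-day water-level drop (m) — to a suitability index (SI) in
[0, 1].  Two constructors cover the shapes used for phytophilic
(sticky-egg) spawners such as carp and crucian carp:

* :func:`make_trapezoid_curve` — the classic preference-curve shape:
  SI = 1 over the observed optimal band, falling linearly to 0 at the
  limits of the observed range.
* :func:`make_drawdown_curve` — the water-level-fluctuation curve
  SI_L(d) = 1 − F(d), where F is the cumulative fraction of eggs
  deposited at depths ≤ d.  An egg is stranded (and dies of
  desiccation) exactly when the waterline falls below its deposition
  depth, so the surviving fraction under a drop d is the fraction of
  eggs deposited deeper than d.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

__all__ = [
    "DepthFrequencyTable",
    "SuitabilityCurve",
    "make_trapezoid_curve",
    "make_drawdown_curve",
    "evaluate",
    "round_half_up",
]

#: variable name used by drawdown curves; checked by the drawdown module.
FIVE_DAY_DROP = "five_day_drop"


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero (display convention, e.g. 0.994)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DepthFrequencyTable:
    """Binned counts of egg-deposition depths.

    Parameters
    ----------
    bins
        Ordered ``(lower, upper)`` depth intervals in metres.  Bins must
        be contiguous, non-overlapping and strictly ascending.
    counts
        Non-negative egg count per bin; the total must be positive.
    """

    bins: tuple[tuple[float, float], ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        bins = tuple((float(lo), float(hi)) for lo, hi in self.bins)
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "bins", bins)
        object.__setattr__(self, "counts", counts)
        if len(bins) != len(counts):
            raise ValueError("bins and counts must have equal length")
        if not bins:
            raise ValueError("frequency table is empty")
        for lo, hi in bins:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bin ({lo}, {hi}): need lower < upper")
        for (_, hi), (lo2, _) in zip(bins, bins[1:]):
            if hi != lo2:
                raise ValueError(
                    f"bins must be contiguous and ascending; gap/overlap at {hi} vs {lo2}"
                )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if sum(counts) <= 0:
            raise ValueError("total count must be positive")

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def edges(self) -> np.ndarray:
        """All bin edges, ``len(bins) + 1`` values."""
        return np.array([self.bins[0][0]] + [hi for _, hi in self.bins])

    def cumulative_fraction(self) -> np.ndarray:
        """Cumulative egg fraction at each bin upper edge (exact, from counts)."""
        return np.cumsum(self.counts) / self.total

    def fractions(self) -> np.ndarray:
        """Per-bin egg fraction (sums to 1 exactly up to float addition)."""
        return np.asarray(self.counts, dtype=float) / self.total


@dataclass(frozen=True)
class SuitabilityCurve:
    """A piecewise-linear suitability curve.

    ``knots`` are ``(x, s)`` pairs with strictly increasing ``x`` and
    ``s`` in [0, 1]; evaluation between knots is exact linear
    interpolation.  ``left_policy`` / ``right_policy`` are the constant
    SI values returned outside the knot span.
    """

    variable: str
    knots: tuple[tuple[float, float], ...]
    units: str = ""
    left_policy: float = 0.0
    right_policy: float = 0.0
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        knots = tuple((float(x), float(s)) for x, s in self.knots)
        object.__setattr__(self, "knots", knots)
        if len(knots) < 2:
            raise ValueError("curve needs at least two knots")
        xs = np.array([x for x, _ in knots])
        ss = np.array([s for _, s in knots])
        if not np.all(np.isfinite(xs)) or not np.all(np.isfinite(ss)):
            raise ValueError("knots must be finite")
        if np.any(np.diff(xs) <= 0):
            raise ValueError("knot x values must be strictly increasing")
        if np.any((ss < 0) | (ss > 1)):
            raise ValueError("knot suitability values must lie in [0, 1]")
        for name in ("left_policy", "right_policy"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
            object.__setattr__(self, name, v)

    @property
    def x(self) -> np.ndarray:
        return np.array([x for x, _ in self.knots])

    @property
    def s(self) -> np.ndarray:
        return np.array([s for _, s in self.knots])

    def __call__(self, x):
        return evaluate(self, x)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "units": self.units,
            "knots": [[x, s] for x, s in self.knots],
            "left_policy": self.left_policy,
            "right_policy": self.right_policy,
            "metadata": dict(self.metadata),
        }

    def to_json(self) -> str:
        """Deterministic JSON encoding; round-trips bit-exactly."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SuitabilityCurve":
        return cls(
            variable=d["variable"],
            units=d.get("units", ""),
            knots=tuple((x, s) for x, s in d["knots"]),
            left_policy=d.get("left_policy", 0.0),
            right_policy=d.get("right_policy", 0.0),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, text: str) -> "SuitabilityCurve":
        return cls.from_dict(json.loads(text))


def make_trapezoid_curve(
    variable: str,
    support: tuple[float, float],
    optimal: tuple[float, float],
    units: str = "",
) -> SuitabilityCurve:
    """Trapezoidal preference curve: SI = 1 on the optimal band, 0 at the
    support limits, linear on the limbs, 0 outside the support.

    If an optimal edge coincides with a support edge the limb on that
    side is degenerate and the shared edge keeps SI = 1 (the
    optimal-band rule wins): e.g. still water is fully suitable when the
    observed velocity optimum starts at 0 m/s.
    """
    s_lo, s_hi = float(support[0]), float(support[1])
    o_lo, o_hi = float(optimal[0]), float(optimal[1])
    if not (s_lo <= o_lo <= o_hi <= s_hi):
        raise ValueError(
            f"need support.lo <= optimal.lo <= optimal.hi <= support.hi, "
            f"got support=({s_lo}, {s_hi}), optimal=({o_lo}, {o_hi})"
        )
    if s_lo == s_hi:
        raise ValueError("support interval is empty")
    knots: list[tuple[float, float]] = []
    if s_lo < o_lo:
        knots.append((s_lo, 0.0))
    if o_lo == o_hi:
        # degenerate optimum: a single knot at SI = 1
        knots.append((o_lo, 1.0))
    else:
        knots.append((o_lo, 1.0))
        knots.append((o_hi, 1.0))
    if o_hi < s_hi:
        knots.append((s_hi, 0.0))
    return SuitabilityCurve(
        variable=variable,
        units=units,
        knots=tuple(knots),
        left_policy=0.0,
        right_policy=0.0,
        metadata={"shape": "trapezoid", "support": [s_lo, s_hi], "optimal": [o_lo, o_hi]},
    )


def make_drawdown_curve(table: DepthFrequencyTable) -> SuitabilityCurve:
    """Water-level-fluctuation suitability curve SI_L from an egg-depth
    frequency table.

    Knots sit at drop d = 0 (SI = 1) and at every bin upper edge, where
    SI = 1 − F(d) with F the cumulative egg fraction at depths ≤ d,
    computed from the raw counts.  A rising or stable water level
    (d ≤ 0) is fully suitable (``left_policy = 1``); a drop beyond the
    deepest deposition depth strands every egg (``right_policy = 0``).
    """
    cum = table.cumulative_fraction()
    knots: list[tuple[float, float]] = [(0.0, 1.0)]
    for (lo, hi), f in zip(table.bins, cum):
        knots.append((hi, float(1.0 - f)))
    # force the terminal knot to exactly zero (cumsum of all counts == total)
    last_x, _ = knots[-1]
    knots[-1] = (last_x, 0.0)
    return SuitabilityCurve(
        variable=FIVE_DAY_DROP,
        units="m",
        knots=tuple(knots),
        left_policy=1.0,
        right_policy=0.0,
        metadata={"shape": "drawdown", "total_eggs": table.total},
    )


def evaluate(curve: SuitabilityCurve, x):
    """Evaluate a curve at scalar or array ``x``; result in [0, 1].

    Linear interpolation between bracketing knots; the left/right
    policies apply outside the knot span.  Non-finite input raises —
    it is never silently mapped to 0.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite input to suitability curve '{curve.variable}'")
    out = np.interp(arr, curve.x, curve.s, left=curve.left_policy, right=curve.right_policy)
    if arr.ndim == 0:
        return float(out)
    return out
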