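"""Packaged reference data.

The egg-depth frequency table comes from a 2019 field survey of carp
(*Cyprinus carpio*) and crucian carp (*Carassius auratus*) spawning
sites in a Three Gorges Reservoir tributary: 163 adhesive eggs binned
by deposition depth, none deeper than 0.8 m.  It is the empirical basis
of the water-level-fluctuation suitability curve SI_L.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .curves import DepthFrequencyTable

__all__ = ["egg_depth_frequency", "default_curves"]


def egg_depth_frequency() -> DepthFrequencyTable:
    """The packaged egg-deposition depth frequency table (n = 163)."""
    ref = resources.files("stickyhab.data").joinpath("egg_depth_frequency.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return DepthFrequencyTable(
        bins=tuple(zip(df["depth_lo_m"], df["depth_hi_m"])),
        counts=tuple(df["count"]),
    )


# Observed preference ranges for carp / crucian carp spawning:
# velocity support 0–0.5 m/s with optimum 0–0.2 m/s; depth support
# 0.2–0.8 m with optimum 0.4–0.6 m; temperature support 15–30 °C with
# optimum 20–23 °C.
VELOCITY_SUPPORT = (0.0, 0.5)
VELOCITY_OPTIMAL = (0.0, 0.2)
DEPTH_SUPPORT = (0.2, 0.8)
DEPTH_OPTIMAL = (0.4, 0.6)
TEMPERATURE_SUPPORT = (15.0, 30.0)
TEMPERATURE_OPTIMAL = (20.0, 23.0)


def default_curves() -> dict:
    """The three hydraulic suitability curves plus the drawdown curve.

    Returns a dict with keys ``velocity``, ``depth``, ``temperature``
    (trapezoidal) and ``drawdown`` (from the packaged egg-depth table).
    """
    from .curves import make_drawdown_curve, make_trapezoid_curve

    return {
        "velocity": make_trapezoid_curve(
            "velocity", VELOCITY_SUPPORT, VELOCITY_OPTIMAL, units="m/s"
        ),
        "depth": make_trapezoid_curve("depth", DEPTH_SUPPORT, DEPTH_OPTIMAL, units="m"),
        "temperature": make_trapezoid_curve(
            "temperature", TEMPERATURE_SUPPORT, TEMPERATURE_OPTIMAL, units="degC"
        ),
        "drawdown": make_drawdown_curve(egg_depth_frequency()),
    }
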