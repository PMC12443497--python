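import numpy as np
import pandas as pd
import pytest

import stickyhab as sh


@pytest.fixture(scope="session")
def egg_table() -> sh.DepthFrequencyTable:
    """Packaged egg-deposition depth frequency table (n = 163)."""
    return sh.egg_depth_frequency()


@pytest.fixture(scope="session")
def drawdown_curve(egg_table) -> sh.SuitabilityCurve:
    return sh.make_drawdown_curve(egg_table)


@pytest.fixture(scope="session")
def hydraulic_curves() -> dict:
    curves = sh.default_curves()
    return {k: curves[k] for k in ("velocity", "depth", "temperature")}


@pytest.fixture()
def stage_constant() -> sh.StageSeries:
    dates = pd.date_range("2019-04-01", periods=20, freq="D")
    return sh.StageSeries(dates=dates, levels=np.full(20, 165.0))


def make_stage(levels, start="2019-04-01") -> sh.StageSeries:
    levels = np.asarray(levels, dtype=float)
    dates = pd.date_range(start, periods=len(levels), freq="D")
    return sh.StageSeries(dates=dates, levels=levels)


@pytest.fixture(scope="session")
def random_field() -> sh.HydroField:
    return sh.gen_hydro_field(sh.FieldSpec(n_cells=500, seed=11), "2019-05-15")
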