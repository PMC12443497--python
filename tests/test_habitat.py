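"""Per-cell HSI composites, classes, and weighted usable area."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stickyhab as sh
from stickyhab.habitat import FIELD_COLUMNS

unit = st.floats(0.0, 1.0)


def make_field(rows, date="2019-05-15"):
    df = pd.DataFrame(rows, columns=FIELD_COLUMNS)
    return sh.HydroField(date=date, cells=df)


class TestComposites:
    @pytest.mark.parametrize("mode", ["geometric_mean", "product"])
    def test_all_optimal_gives_one(self, mode):
        assert sh.spawning_hsi(1, 1, 1, mode=mode) == 1.0
        assert sh.hatching_hsi(1, 1, 1, 1, mode=mode) == 1.0

    @given(v=unit, h=unit, t=unit, l=unit, which=st.integers(0, 3))
    @settings(max_examples=200, deadline=None)
    @pytest.mark.parametrize("mode", ["geometric_mean", "product"])
    def test_any_zero_factor_annihilates(self, mode, v, h, t, l, which):
        factors = [v, h, t, l]
        factors[which] = 0.0
        assert sh.hatching_hsi(*factors, mode=mode) == 0.0
        if which < 3:
            assert sh.spawning_hsi(*factors[:3], mode=mode) == 0.0

    def test_equal_factors_geometric_mean_identity(self):
        assert sh.spawning_hsi(0.5, 0.5, 0.5) == pytest.approx(0.5)
        assert sh.hatching_hsi(0.5, 0.5, 0.5, 0.5) == pytest.approx(0.5)

    def test_fourth_root_of_near_unit_si_l(self):
        assert sh.hatching_hsi(1, 1, 1, 0.994) == pytest.approx(0.994 ** 0.25)
        assert round(sh.hatching_hsi(1, 1, 1, 0.994), 4) == 0.9985

    def test_product_mode_si_l_identity(self):
        """With SI_L = 1, product-mode hatching equals spawning exactly."""
        assert sh.hatching_hsi(0.5, 0.5, 0.5, 1, mode="product") == sh.spawning_hsi(
            0.5, 0.5, 0.5, mode="product"
        )

    @given(v=unit, h=unit, t=unit, l=unit, bump=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    @pytest.mark.parametrize("mode", ["geometric_mean", "product"])
    def test_monotone_in_each_factor(self, mode, v, h, t, l, bump):
        base = sh.hatching_hsi(v, h, t, l, mode=mode)
        assert sh.hatching_hsi(min(1.0, v + bump), h, t, l, mode=mode) >= base
        assert sh.hatching_hsi(v, h, t, min(1.0, l + bump), mode=mode) >= base

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sh.spawning_hsi(1.2, 0.5, 0.5)
        with pytest.raises(ValueError):
            sh.hatching_hsi(0.5, 0.5, 0.5, -0.1)
        with pytest.raises(ValueError):
            sh.spawning_hsi(0.5, 0.5, 0.5, mode="median")


class TestClassify:
    @pytest.mark.parametrize(
        "hsi, label",
        [
            (0.15, "very_low"),
            (0.2, "low"),  # boundaries go to the upper class
            (0.4, "medium"),
            (0.59, "medium"),
            (0.6, "high"),
            (0.8, "very_high"),
            (1.0, "very_high"),
            (0.0, "very_low"),
        ],
    )
    def test_class_bins(self, hsi, label):
        assert sh.classify_hsi(hsi) == label

    def test_vectorized(self):
        out = sh.classify_hsi(np.array([0.1, 0.3, 0.5, 0.7, 0.9]))
        assert list(out) == list(sh.CLASS_LABELS)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            sh.classify_hsi(1.1)


class TestCellSuitabilities:
    def test_jointly_optimal_cell(self, hydraulic_curves):
        field = make_field([("a", 10.0, 0.1, 0.5, 21.0)])
        suit = sh.cell_suitabilities(field, hydraulic_curves, si_l=1.0)
        row = suit.iloc[0]
        assert row.si_v == row.si_h == row.si_t == 1.0
        assert row.hsi_spawn == 1.0 and row.class_spawn == "very_high"

    def test_velocity_beyond_support(self, hydraulic_curves):
        field = make_field([("a", 10.0, 0.6, 0.5, 21.0)])
        suit = sh.cell_suitabilities(field, hydraulic_curves, si_l=1.0)
        assert suit.iloc[0].si_v == 0.0 and suit.iloc[0].hsi_spawn == 0.0

    def test_limb_midpoints(self, hydraulic_curves):
        field = make_field([("a", 10.0, 0.35, 0.3, 17.5)])
        suit = sh.cell_suitabilities(field, hydraulic_curves, si_l=1.0)
        row = suit.iloc[0]
        assert (row.si_v, row.si_h, row.si_t) == pytest.approx((0.5, 0.5, 0.5))

    def test_dry_cell_has_zero_hsi(self, hydraulic_curves):
        field = make_field([("a", 10.0, 0.0, 0.0, 21.0)])
        suit = sh.cell_suitabilities(field, hydraulic_curves, si_l=1.0)
        assert suit.iloc[0].si_h == 0.0 and suit.iloc[0].hsi_hatch == 0.0

    def test_missing_curve_and_bad_si_l(self, hydraulic_curves):
        field = make_field([("a", 10.0, 0.1, 0.5, 21.0)])
        with pytest.raises(ValueError, match="missing"):
            sh.cell_suitabilities(field, {"velocity": hydraulic_curves["velocity"]}, 1.0)
        with pytest.raises(ValueError, match="si_l"):
            sh.cell_suitabilities(field, hydraulic_curves, si_l=1.5)


class TestWUA:
    def test_hand_computed(self):
        assert sh.weighted_usable_area([10, 20], [0.5, 0.25]) == pytest.approx(10.0)
        assert sh.weighted_usable_area([10, 20], [0.0, 0.0]) == 0.0

    def test_matches_brute_force_on_random_cells(self):
        rng = np.random.default_rng(17)
        areas = rng.uniform(1, 500, 1000)
        hsi = rng.uniform(0, 1, 1000)
        oracle = sum(a * h for a, h in zip(areas, hsi))
        assert sh.weighted_usable_area(areas, hsi) == pytest.approx(oracle, rel=1e-12)

    def test_wua_bounded_by_total_area(self, random_field, hydraulic_curves):
        suit = sh.cell_suitabilities(random_field, hydraulic_curves, si_l=0.7)
        wua = sh.weighted_usable_area(suit.area_m2, suit.hsi_spawn)
        assert 0 <= wua <= random_field.total_area

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sh.weighted_usable_area([], [])

    @pytest.mark.parametrize("si_l_lo, si_l_hi", [(0.2, 0.8), (0.0, 1.0), (0.5, 0.6)])
    def test_hatching_wua_monotone_in_si_l(self, random_field, hydraulic_curves, si_l_lo, si_l_hi):
        def wua_h(s):
            suit = sh.cell_suitabilities(random_field, hydraulic_curves, si_l=s)
            return sh.weighted_usable_area(suit.area_m2, suit.hsi_hatch)

        assert wua_h(si_l_lo) <= wua_h(si_l_hi)

    @pytest.mark.parametrize("si_l", [0.0, 0.3, 0.7, 1.0])
    def test_product_mode_ordering(self, random_field, hydraulic_curves, si_l):
        """Product mode: hatching WUA ≤ spawning WUA, equal iff SI_L = 1."""
        suit = sh.cell_suitabilities(random_field, hydraulic_curves, si_l=si_l, mode="product")
        wua_s = sh.weighted_usable_area(suit.area_m2, suit.hsi_spawn)
        wua_h = sh.weighted_usable_area(suit.area_m2, suit.hsi_hatch)
        if si_l == 1.0:
            assert wua_h == pytest.approx(wua_s)
        else:
            assert wua_h <= wua_s
            if wua_s > 0:
                assert wua_h < wua_s


class TestClassAreaTable:
    def test_single_class(self, hydraulic_curves):
        # all cells jointly optimal, SI_L = 1 -> everything very_high
        field = make_field([("a", 10.0, 0.1, 0.5, 21.0), ("b", 30.0, 0.15, 0.45, 22.0)])
        suit = sh.cell_suitabilities(field, hydraulic_curves, si_l=1.0)
        tab = sh.class_area_table(suit)
        assert tab.loc["very_high", "spawning"] == 1.0
        assert tab.loc["very_high", "change_pct"] == 0.0

    def test_fractions_sum_to_one(self, random_field, hydraulic_curves):
        suit = sh.cell_suitabilities(random_field, hydraulic_curves, si_l=0.5)
        tab = sh.class_area_table(suit)
        assert tab["spawning"].sum() == pytest.approx(1.0, abs=1e-12)
        assert tab["hatching"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_drawdown_shrinks_high_suitability_area(self, random_field, hydraulic_curves):
        """Applying SI_L = 0.2 demotes cells, so high + very_high hatching
        area cannot exceed the spawning one (product mode)."""
        suit = sh.cell_suitabilities(random_field, hydraulic_curves, si_l=0.2, mode="product")
        tab = sh.class_area_table(suit)
        hi_spawn = tab.loc[["high", "very_high"], "spawning"].sum()
        hi_hatch = tab.loc[["high", "very_high"], "hatching"].sum()
        assert hi_hatch < hi_spawn


class TestSummarize:
    def _fields(self, n_dates=3):
        return {
            pd.Timestamp("2019-05-01") + pd.Timedelta(days=i): sh.gen_hydro_field(
                sh.FieldSpec(n_cells=300, seed=20 + i), f"2019-05-0{i+1}"
            )
            for i in range(n_dates)
        }

    def test_product_mode_identity_at_unit_si_l(self, hydraulic_curves):
        fields = self._fields()
        si_l = {d: 1.0 for d in fields}
        out = sh.summarize(fields, hydraulic_curves, si_l, mode="product")
        assert len(out) == 3
        for s in out:
            assert s.wua_hatch == pytest.approx(s.wua_spawn)
            assert s.wua_reduction_pct == pytest.approx(0.0)

    def test_zero_si_l_gives_total_reduction(self, hydraulic_curves):
        fields = self._fields(1)
        out = sh.summarize(fields, hydraulic_curves, {d: 0.0 for d in fields})
        assert out[0].wua_hatch == 0.0
        assert out[0].wua_reduction_pct == pytest.approx(100.0)

    def test_declining_stage_scenario_always_reduces(self, hydraulic_curves, drawdown_curve):
        """An April–May drawdown keeps SI_L < 1, so hatching WUA sits
        strictly below spawning WUA on every day (product mode)."""
        spec = sh.RegimeSpec.post_dam(seed=9)
        stage = sh.gen_stage_series(spec, "2019-04-01", "2019-04-20")
        dd = sh.si_l_series(stage, drawdown_curve)
        fields = {
            d: sh.gen_hydro_field(sh.FieldSpec(n_cells=300, seed=i), d)
            for i, d in enumerate(dd.dates[:5])
        }
        si_l = {d: float(s) for d, s in zip(dd.dates[:5], dd.si_l[:5])}
        out = sh.summarize(fields, hydraulic_curves, si_l, mode="product")
        for s in out:
            assert s.wua_hatch < s.wua_spawn
            assert s.wua_reduction_pct > 0

    def test_date_misalignment_raises(self, hydraulic_curves):
        fields = self._fields(2)
        with pytest.raises(ValueError, match="misalignment"):
            sh.summarize(fields, hydraulic_curves, {list(fields)[0]: 1.0})


class TestHydroFieldValidation:
    def test_rejects_nonpositive_area(self):
        with pytest.raises(ValueError, match="area"):
            make_field([("a", 0.0, 0.1, 0.5, 21.0)])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_field([("a", 1.0, 0.1, 0.5, 21.0), ("a", 1.0, 0.1, 0.5, 21.0)])

    def test_rejects_empty(self):
        with pytest.raises(ValueError, match="no cells"):
            make_field([])
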