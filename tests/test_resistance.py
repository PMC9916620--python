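"""Resistance tables, margin scenario recoding, and rasterization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corridorscape.grids import LandCoverGrid
from corridorscape.resistance import (
    DEFAULT_EXPERT_OVERRIDES,
    RecodingError,
    ResistanceError,
    ResistanceTable,
    apply_margin_scenario,
    build_resistance_table,
    load_reference_table,
    load_to_resistance,
    rasterize_resistance,
    raw_resistance,
    reference_resistance_table,
    round_half_up,
    scenario_resistance_grid,
)


class TestLoadToResistance:
    def test_pomegranate_worked_example(self):
        # pomegranate load / urban load * 8 = 11.8 -> Table value 12
        assert load_to_resistance(2_220_400_221, 1_500_895_028, 8) == 12

    def test_anchor_identity(self):
        for a in (1, 8, 37, 100):
            assert load_to_resistance(1_500_895_028, 1_500_895_028, a) == a

    def test_zero_load_floors_at_natural_baseline(self):
        assert load_to_resistance(0, 1_500_895_028, 8) == 1

    def test_cap_at_100(self):
        assert load_to_resistance(1e12, 1.0, 8) == 100

    def test_nonpositive_urban_load_rejected(self):
        with pytest.raises(ResistanceError):
            load_to_resistance(1.0, 0.0, 8)

    @pytest.mark.parametrize("x,expected", [(11.76, 12), (11.5, 12), (2.5, 3), (2.49, 2)])
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected

    @settings(deadline=None, max_examples=50)
    @given(load=st.floats(1e6, 1e12), urban=st.floats(1e6, 1e12), anchor=st.integers(1, 12))
    def test_linearity_before_rounding(self, load, urban, anchor):
        raw = raw_resistance(load, urban, anchor)
        assert raw_resistance(10 * load, urban, anchor) == pytest.approx(10 * raw, rel=1e-12)


class TestBuildResistanceTable:
    def _loads_matching_reference_crops(self):
        """Scenario loads constructed so the computed per-level resistances
        equal the published table's 24 crop rows exactly."""
        ref = load_reference_table()
        crops = ref[ref["agriculture"] == "Y"]
        anchors = {"low": 7, "medium": 8, "high": 9}
        rows = {"urban": {lvl: 1.0 for lvl in anchors}}
        for lc, row in crops.iterrows():
            rows[lc] = {lvl: row[lvl] / anchors[lvl] for lvl in anchors}
        return pd.DataFrame.from_dict(rows, orient="index")

    def test_other_row_matches_published_crop_average(self):
        # mean of the 24 crop rows: 19.375, 22.04, 24.58 -> rounds to 19/22/25
        table = build_resistance_table(self._loads_matching_reference_crops())
        other = table.table.loc["other"]
        assert (other["low"], other["medium"], other["high"]) == (19, 22, 25)
        ref_other = load_reference_table().loc["Other"]
        assert (ref_other["low"], ref_other["medium"], ref_other["high"]) == (19, 22, 25)

    def test_computed_rows_reproduce_reference_values(self):
        table = build_resistance_table(self._loads_matching_reference_crops())
        ref = load_reference_table()
        for lc, row in ref[ref["agriculture"] == "Y"].iterrows():
            for lvl in ("low", "medium", "high"):
                assert table.value(lc, lvl) == row[lvl], (lc, lvl)

    def test_overrides_only_flagged_expert(self):
        loads = pd.DataFrame(
            {"low": [1.0], "medium": [1.0], "high": [1.0]},
            index=pd.Index(["urban"], name="land_class"),
        )
        table = build_resistance_table(loads)
        ov = table.table.drop(index="urban")
        assert (ov["provenance"] == "expert").all()
        assert set(ov.index) == set(DEFAULT_EXPERT_OVERRIDES.index)

    def test_other_is_mean_of_computed_crops(self):
        loads = pd.DataFrame(
            {
                "low": [1.0, 10 / 7, 20 / 7],
                "medium": [1.0, 10 / 8, 20 / 8],
                "high": [1.0, 10 / 9, 20 / 9],
            },
            index=pd.Index(["urban", "c1", "c2"], name="land_class"),
        )
        table = build_resistance_table(loads)
        assert table.value("other", "medium") == 15

    def test_out_of_range_override_rejected(self):
        bad = DEFAULT_EXPERT_OVERRIDES.copy()
        bad.loc["water"] = [120, 120, 120]
        loads = pd.DataFrame(
            {"low": [1.0], "medium": [1.0], "high": [1.0]},
            index=pd.Index(["urban"], name="land_class"),
        )
        with pytest.raises(ResistanceError):
            build_resistance_table(loads, overrides=bad)

    def test_level_ordering_always_holds(self, mini_resistance_table):
        t = mini_resistance_table.table
        assert ((t["low"] <= t["medium"]) & (t["medium"] <= t["high"])).all()


def _toy_grid(codes, roles, names, **kw):
    return LandCoverGrid(
        codes=np.asarray(codes, dtype=np.int32),
        cell_size_m=30.0,
        class_roles=roles,
        class_names=names,
        **kw,
    )


class TestMarginScenarios:
    def test_current_is_identity(self, mini_landscape):
        grid, _ = mini_landscape
        out = apply_margin_scenario(grid, "current")
        assert np.array_equal(out.codes, grid.codes)

    def test_restored_conserves_cells(self, mini_landscape):
        grid, _ = mini_landscape
        n_margin = grid.role_mask("margin").sum()
        n_natural = grid.role_mask("natural").sum()
        out = apply_margin_scenario(grid, "restored")
        assert out.role_mask("margin").sum() == 0
        assert out.role_mask("natural").sum() == n_natural + n_margin
        # non-margin cells untouched
        untouched = ~grid.role_mask("margin")
        assert np.array_equal(out.codes[untouched], grid.codes[untouched])

    def test_none_assigns_nearest_crop_row_major_on_ties(self):
        # margin cell at (3,3) equidistant (2 cells) from crops at (3,1) and
        # (3,5); the row-major-first crop cell (3,1) must win.
        codes = np.full((7, 7), 2, dtype=np.int32)
        codes[3, 1] = 10
        codes[3, 5] = 11
        codes[3, 3] = 3
        codes[3, 2] = 3  # adjacent margin, nearest crop is unambiguous
        grid = _toy_grid(
            codes,
            {2: "grassland", 3: "margin", 10: "crop", 11: "crop"},
            {2: "grassland", 3: "agricultural_margin", 10: "a", 11: "b"},
        )
        out = apply_margin_scenario(grid, "none")
        assert out.codes[3, 3] == 10  # tie broken toward lower flat index
        assert out.codes[3, 2] == 10
        assert not out.role_mask("margin").any()

    def test_none_without_crops_rejected(self):
        codes = np.full((4, 4), 2, dtype=np.int32)
        codes[1, 1] = 3
        grid = _toy_grid(
            codes,
            {2: "grassland", 3: "margin"},
            {2: "grassland", 3: "agricultural_margin"},
        )
        with pytest.raises(RecodingError):
            apply_margin_scenario(grid, "none")

    def test_restored_pointwise_below_current(self, mini_landscape, mini_resistance_table):
        grid, _ = mini_landscape
        for level in ("low", "medium", "high"):
            restored = scenario_resistance_grid(grid, mini_resistance_table, "restored", level)
            current = scenario_resistance_grid(grid, mini_resistance_table, "current", level)
            assert (restored.values <= current.values).all()


class TestRasterize:
    def test_uniform_natural_grid_is_all_ones(self):
        grid = _toy_grid(np.ones((3, 3)), {1: "natural"}, {1: "Natural"})
        out = rasterize_resistance(grid, reference_resistance_table(), "medium")
        assert (out.values == 1).all()

    def test_reference_pomegranate_and_water_values(self):
        codes = np.array([[1, 1], [2, 2]], dtype=np.int32)
        grid = _toy_grid(
            codes,
            {1: "crop", 2: "water"},
            {1: "Pomegranates", 2: "Water"},
        )
        out = rasterize_resistance(grid, reference_resistance_table(), "medium")
        assert set(np.unique(out.values)) == {12.0, 100.0}
        assert (out.values[0] == 12).all() and (out.values[1] == 100).all()

    def test_nodata_propagates(self):
        codes = np.array([[1, 1], [1, -9999]], dtype=np.int32)
        grid = _toy_grid(codes, {1: "natural"}, {1: "Natural"}, nodata_code=-9999)
        out = rasterize_resistance(grid, reference_resistance_table(), "medium")
        assert np.isnan(out.values[1, 1])
        assert np.isfinite(out.values).sum() == 3

    def test_unmapped_code_names_the_code(self):
        codes = np.array([[1, 99], [1, 1]], dtype=np.int32)
        grid = _toy_grid(codes, {1: "natural", 99: "crop"}, {1: "Natural", 99: "durian"})
        with pytest.raises(ResistanceError, match="99|durian"):
            rasterize_resistance(grid, reference_resistance_table(), "medium")

    def test_lookup_round_trip_recovers_class_map(self, mini_landscape, mini_resistance_table):
        grid, _ = mini_landscape
        level = "medium"
        rg = rasterize_resistance(grid, mini_resistance_table, level)
        value_of = {
            grid.class_names[c]: mini_resistance_table.value(grid.class_names[c], level)
            for c in np.unique(grid.codes)
        }
        # reverse lookup is only well-defined where values are unique
        from collections import Counter

        counts = Counter(value_of.values())
        for code in np.unique(grid.codes):
            name = grid.class_names[code]
            if counts[value_of[name]] == 1:
                assert (rg.values[grid.codes == code] == value_of[name]).all()
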