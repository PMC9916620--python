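"""Connectivity summary statistics on hand-built path sets."""

import numpy as np
import pytest

from corridorscape.cost import LeastCostPath
from corridorscape.grids import LandCoverGrid
from corridorscape.metrics import (
    MetricsError,
    commonality_across_levels,
    landcover_composition,
    mean_convergent_paths,
    mean_distance_to_path,
    total_path_length,
    unique_path_length,
)

CELL = 30.0


def make_path(cells, cell_size=CELL, **meta):
    length = 0.0
    for (r1, c1), (r2, c2) in zip(cells[:-1], cells[1:]):
        length += cell_size * (np.sqrt(2.0) if (r1 != r2 and c1 != c2) else 1.0)
    return LeastCostPath(cells=list(cells), total_cost=0.0, euclidean_length_m=length, meta=meta)


def hpath(row, c0, c1):
    step = 1 if c1 >= c0 else -1
    return make_path([(row, c) for c in range(c0, c1 + step, step)])


FULL = np.ones((9, 12), dtype=bool)


class TestTotalPathLength:
    def test_ten_orthogonal_moves(self):
        assert total_path_length([hpath(0, 0, 10)]) == pytest.approx(0.3)

    def test_empty_collection(self):
        assert total_path_length([]) == 0.0

    def test_duplicates_count_twice(self):
        p = hpath(0, 0, 10)
        assert total_path_length([p, p]) == pytest.approx(0.6)


class TestUniquePathLength:
    def test_identical_paths_deduplicate(self):
        p = hpath(2, 0, 10)
        assert unique_path_length([p, p], FULL, CELL) == pytest.approx(
            unique_path_length([p], FULL, CELL)
        )

    def test_partial_overlap_counts_union(self):
        # both paths use 10 moves; they share 4 moves -> 16 distinct moves
        a = hpath(2, 0, 10)
        b = make_path([(3, 0), (3, 1), (3, 2), (2, 2), (2, 3), (2, 4), (2, 5), (2, 6),
                       (3, 6), (3, 7), (3, 8)])
        union_km = unique_path_length([a, b], FULL, CELL)
        # independent enumeration of the union
        moves = set()
        for p in (a, b):
            for m in p.moves():
                (r1, c1), (r2, c2) = m
                key = tuple(sorted([(r1, c1), (r2, c2)]))
                moves.add(key)
        expected = sum(
            CELL * (np.sqrt(2.0) if (m[0][0] != m[1][0] and m[0][1] != m[1][1]) else 1.0)
            for m in moves
        ) / 1000.0
        assert union_km == pytest.approx(expected, rel=1e-12)

    def test_shared_four_of_ten_orthogonal_moves(self):
        a = hpath(2, 0, 10)
        b_cells = [(2, 0), (2, 1), (2, 2), (2, 3), (2, 4), (3, 4), (3, 5), (3, 6),
                   (3, 7), (3, 8), (3, 9)]
        b = make_path(b_cells)
        # b shares the first 4 orthogonal moves of a: (10 + 10 - 4) x 30 m
        got = unique_path_length([a, b], FULL, CELL)
        assert got == pytest.approx((10 + 10 - 4) * CELL / 1000.0, rel=1e-12)

    def test_reversal_invariance(self):
        a = hpath(2, 0, 10)
        rev = make_path(list(reversed(a.cells)))
        assert unique_path_length([a], FULL, CELL) == unique_path_length([rev], FULL, CELL)
        assert unique_path_length([a, rev], FULL, CELL) == unique_path_length([a], FULL, CELL)

    def test_outside_mask_is_zero(self):
        mask = np.zeros_like(FULL)
        assert unique_path_length([hpath(2, 0, 10)], mask, CELL) == 0.0

    def test_misaligned_grid_rejected(self):
        with pytest.raises(MetricsError):
            unique_path_length([hpath(20, 0, 5)], FULL, CELL)


class TestMeanDistanceToPath:
    def test_full_coverage_gives_zero(self):
        paths = [hpath(r, 0, 11) for r in range(9)]
        assert mean_distance_to_path(paths, FULL, CELL) == 0.0

    def test_single_column_strip(self):
        # 1-row strip of 5 columns with a full-height path in column 0:
        # mean distance = mean(0,1,2,3,4) cells = 0.06 km at 30 m
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 0:5] = True
        path = make_path([(r, 0) for r in range(5)])
        got = mean_distance_to_path([path], mask, CELL)
        assert got == pytest.approx(np.mean([0, 1, 2, 3, 4]) * CELL / 1000.0)

    def test_cell_size_scale_equivariance(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 0:5] = True
        path = make_path([(r, 0) for r in range(5)])
        assert mean_distance_to_path([path], mask, 2 * CELL) == pytest.approx(
            2 * mean_distance_to_path([path], mask, CELL)
        )

    def test_no_paths_is_undefined(self):
        with pytest.raises(MetricsError):
            mean_distance_to_path([], FULL, CELL)


class TestMeanConvergentPaths:
    def test_single_path(self):
        assert mean_convergent_paths([hpath(2, 0, 10)], FULL) == 1.0

    def test_two_crossing_paths(self):
        # two 9-cell paths sharing exactly one cell: (16*1 + 1*2)/17
        a = hpath(4, 0, 8)  # row 4, cols 0..8
        b = make_path([(r, 4) for r in range(9)])  # col 4, rows 0..8
        got = mean_convergent_paths([a, b], FULL)
        assert got == pytest.approx((16 * 1 + 1 * 2) / 17)

    def test_k_identical_paths(self):
        p = hpath(2, 0, 10)
        for k in (2, 5):
            assert mean_convergent_paths([p] * k, FULL) == float(k)

    def test_no_inner_cells_undefined(self):
        with pytest.raises(MetricsError):
            mean_convergent_paths([hpath(2, 0, 10)], np.zeros_like(FULL))


class TestCommonality:
    def test_identical_sets(self):
        p = [hpath(2, 0, 10)]
        out = commonality_across_levels(
            {"low": p, "medium": p, "high": p}, CELL, FULL.shape
        )
        assert out == {"three_levels": 1.0, "two_levels": 0.0, "one_level": 0.0}

    def test_pairwise_disjoint_sets(self):
        out = commonality_across_levels(
            {"low": [hpath(1, 0, 5)], "medium": [hpath(3, 0, 5)], "high": [hpath(5, 0, 5)]},
            CELL,
            FULL.shape,
        )
        assert out["one_level"] == pytest.approx(1.0)
        assert out["three_levels"] == 0.0

    def test_hand_built_mixture(self):
        shared = hpath(2, 0, 10)  # 10 moves in all three levels
        two = hpath(4, 0, 4)  # 4 moves in low+medium only
        solo = hpath(6, 0, 5)  # 5 moves in high only
        out = commonality_across_levels(
            {
                "low": [shared, two],
                "medium": [shared, two],
                "high": [shared, solo],
            },
            CELL,
            FULL.shape,
        )
        assert out["three_levels"] == pytest.approx(10 / 19)
        assert out["two_levels"] == pytest.approx(4 / 19)
        assert out["one_level"] == pytest.approx(5 / 19)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-9)

    def test_missing_level_rejected(self):
        with pytest.raises(MetricsError):
            commonality_across_levels({"low": [], "medium": []}, CELL, FULL.shape)


class TestComposition:
    def _grid(self, codes):
        return LandCoverGrid(
            codes=np.asarray(codes, dtype=np.int32),
            cell_size_m=CELL,
            class_roles={1: "natural", 3: "margin", 10: "crop"},
            class_names={1: "natural", 3: "agricultural_margin", 10: "rice"},
        )

    def test_all_natural(self):
        grid = self._grid(np.ones((8, 12)))
        comp = landcover_composition([hpath(2, 0, 10)], grid)
        assert dict(comp) == {"natural": 1.0}

    def test_margin_entries_fraction(self):
        codes = np.ones((8, 12))
        codes[2, 3] = 3
        codes[2, 6] = 3
        codes[2, 9] = 3
        grid = self._grid(codes)
        comp = landcover_composition([hpath(2, 0, 10)], grid)
        assert comp["margin"] == pytest.approx(0.3)
        assert comp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_first_cell_contributes_nothing(self):
        codes = np.ones((8, 12))
        codes[2, 0] = 10  # path starts on crop, never re-enters it
        grid = self._grid(codes)
        comp = landcover_composition([hpath(2, 0, 10)], grid)
        assert "crop" not in comp.index

    def test_unmapped_class_rejected(self):
        grid = self._grid(np.ones((8, 12)))
        grid.codes[2, 5] = 77
        with pytest.raises(MetricsError):
            landcover_composition([hpath(2, 0, 10)], grid)

    def test_order_invariance(self):
        codes = np.ones((8, 12))
        codes[2, 5] = 3
        grid = self._grid(codes)
        a, b = hpath(2, 0, 10), hpath(3, 0, 6)
        c1 = landcover_composition([a, b], grid)
        c2 = landcover_composition([b, a], grid)
        assert dict(c1) == dict(c2)
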