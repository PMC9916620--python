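"""Raster cost-distance and least-cost paths on the 8-connected cell graph.

This re-implements the classic GIS Cost Distance / Cost Path operation:
moving between two neighbouring cells costs the mean of their resistances
times the geometric move length (1 cell orthogonally, √2 diagonally), and
the accumulated cost of a cell is the minimum total cost over 8-connected
paths from any source cell — computed with Dijkstra's algorithm on the
sparse cell graph.  Accumulated costs are therefore in "cells traversed x
cost" units; Euclidean path lengths are reported separately in meters.

Conventions (documented rather than inherited from any particular GIS):
nodata cells are impassable; ties between equal-cost predecessors are broken
by the lowest row-major (flat) cell index, so backlink grids and traced
paths are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

#: backlink direction codes: 1 = E then clockwise through 8 = NE.
#: ``DIRECTIONS[code]`` is the (drow, dcol) offset from a cell to its
#: predecessor.
DIRECTIONS: dict[int, tuple[int, int]] = {
    1: (0, 1),
    2: (1, 1),
    3: (1, 0),
    4: (1, -1),
    5: (0, -1),
    6: (-1, -1),
    7: (-1, 0),
    8: (-1, 1),
}


class CostEngineError(ValueError):
    pass


class UnreachableError(ValueError):
    """Requested destination has infinite accumulated cost."""


@dataclass
class LeastCostPath:
    """A traced least-cost route, ordered source -> destination."""

    cells: list[tuple[int, int]]
    total_cost: float
    euclidean_length_m: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cells)

    def moves(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        return list(zip(self.cells[:-1], self.cells[1:]))


@dataclass
class CostSurface:
    """Accumulated cost and backlink grids from a set of source cells."""

    accumulated: np.ndarray
    backlink: np.ndarray
    sources: frozenset[tuple[int, int]]
    cell_size_m: float = 1.0

    def trace_path(self, destination: tuple[int, int]) -> LeastCostPath:
        return trace_path(self, destination)


class CostGraph:
    """Sparse 8-connected cell graph for one resistance surface.

    Build once per resistance grid; reuse for any number of source sets.
    """

    def __init__(self, resistance: np.ndarray, cell_size_m: float = 1.0):
        resistance = np.asarray(resistance, dtype=float)
        if resistance.ndim != 2:
            raise CostEngineError("resistance grid must be 2-D")
        self.resistance = resistance
        self.cell_size_m = float(cell_size_m)
        self.shape = resistance.shape
        self.valid = np.isfinite(resistance)
        if self.valid.any() and resistance[self.valid].min() <= 0:
            raise CostEngineError("resistance must be positive")
        self._graph = self._build_graph()

    def _build_graph(self):
        nrows, ncols = self.shape
        n = nrows * ncols
        res = self.resistance
        valid = self.valid
        rows_idx = np.arange(n).reshape(self.shape)
        src_list, dst_list, w_list = [], [], []
        # one direction per undirected edge: E, S, SE, SW
        for (dr, dc), length in (
            ((0, 1), 1.0),
            ((1, 0), 1.0),
            ((1, 1), sqrt(2.0)),
            ((1, -1), sqrt(2.0)),
        ):
            r0 = slice(max(0, -dr), nrows - max(0, dr))
            c0 = slice(max(0, -dc), ncols - max(0, dc))
            r1 = slice(max(0, dr), nrows + min(0, dr))
            c1 = slice(max(0, dc), ncols + min(0, dc))
            ok = valid[r0, c0] & valid[r1, c1]
            a = rows_idx[r0, c0][ok]
            b = rows_idx[r1, c1][ok]
            w = 0.5 * (res[r0, c0][ok] + res[r1, c1][ok]) * length
            src_list.append(a)
            dst_list.append(b)
            w_list.append(w)
        src = np.concatenate(src_list)
        dst = np.concatenate(dst_list)
        w = np.concatenate(w_list)
        return coo_matrix((w, (src, dst)), shape=(n, n)).tocsr()

    @staticmethod
    def move_cost(res_a: float, res_b: float, diagonal: bool) -> float:
        """Cost of one move: mean resistance times geometric length."""
        return 0.5 * (res_a + res_b) * (sqrt(2.0) if diagonal else 1.0)

    def cost_distance(self, sources: Iterable[tuple[int, int]]) -> CostSurface:
        """Accumulated-cost and backlink grids from ``sources``.

        Unreached and nodata cells carry ``inf``; backlink 0 marks sources
        and unreached cells.
        """
        sources = [tuple(map(int, s)) for s in sources]
        if not sources:
            raise CostEngineError("source set is empty")
        nrows, ncols = self.shape
        on_valid = [s for s in sources if self.valid[s]]
        if not on_valid:
            raise CostEngineError("all sources fall on nodata cells")
        flat_sources = sorted({r * ncols + c for r, c in on_valid})
        dist = dijkstra(
            self._graph, directed=False, indices=flat_sources, min_only=True
        )
        acc = dist.reshape(self.shape)
        backlink = self._derive_backlinks(acc, flat_sources)
        return CostSurface(
            accumulated=acc,
            backlink=backlink,
            sources=frozenset(on_valid),
            cell_size_m=self.cell_size_m,
        )

    def _derive_backlinks(self, acc: np.ndarray, flat_sources: Sequence[int]) -> np.ndarray:
        """Backlink codes re-derived from the accumulated surface.

        For each reached non-source cell, the predecessor is the neighbour
        minimizing (neighbour cost + move cost); among equal-cost
        predecessors the lowest flat index wins.
        """
        nrows, ncols = self.shape
        n = nrows * ncols
        # nodata as inf (not nan) so candidate costs never turn nan
        res = np.where(self.valid, self.resistance, np.inf)
        cand_cost = np.full((8, nrows, ncols), np.inf)
        cand_flat = np.full((8, nrows, ncols), n, dtype=np.int64)
        flat_idx = np.arange(n).reshape(self.shape)
        for k, (code, (dr, dc)) in enumerate(sorted(DIRECTIONS.items())):
            length = sqrt(2.0) if dr and dc else 1.0
            r0 = slice(max(0, -dr), nrows - max(0, dr))
            c0 = slice(max(0, -dc), ncols - max(0, dc))
            rp = slice(max(0, dr), nrows + min(0, dr))
            cp = slice(max(0, dc), ncols + min(0, dc))
            move = 0.5 * (res[r0, c0] + res[rp, cp]) * length
            cand_cost[k][r0, c0] = acc[rp, cp] + move
            cand_flat[k][r0, c0] = flat_idx[rp, cp]
        best = cand_cost.min(axis=0)
        # ties within floating-point slack of the minimum
        tol = 1e-12 * np.maximum(1.0, np.abs(best))
        is_cand = cand_cost <= best + tol
        pred_choice = np.where(is_cand, cand_flat, n)
        k_best = pred_choice.argmin(axis=0)
        codes = np.array(sorted(DIRECTIONS))[k_best]
        backlink = np.where(np.isfinite(acc), codes, 0).astype(np.int8)
        src_mask = np.zeros(n, dtype=bool)
        src_mask[list(flat_sources)] = True
        backlink[src_mask.reshape(self.shape)] = 0
        return backlink


def cost_distance(
    resistance: np.ndarray,
    sources: Iterable[tuple[int, int]],
    cell_size_m: float = 1.0,
) -> CostSurface:
    """One-shot convenience wrapper around :class:`CostGraph`."""
    return CostGraph(resistance, cell_size_m).cost_distance(sources)


def trace_path(surface: CostSurface, destination: tuple[int, int]) -> LeastCostPath:
    """Follow backlinks from ``destination`` to a source cell.

    Raises :class:`UnreachableError` when the destination was never reached.
    """
    dest = tuple(map(int, destination))
    acc = surface.accumulated
    if not np.isfinite(acc[dest]):
        raise UnreachableError(f"destination {dest} is unreachable from the sources")
    cells = [dest]
    r, c = dest
    length = 0.0
    guard = acc.size + 1
    while surface.backlink[r, c] != 0:
        dr, dc = DIRECTIONS[int(surface.backlink[r, c])]
        r, c = r + dr, c + dc
        length += surface.cell_size_m * (sqrt(2.0) if dr and dc else 1.0)
        cells.append((r, c))
        guard -= 1
        if guard == 0:  # pragma: no cover - defends against a corrupt grid
            raise CostEngineError("backlink cycle detected")
    cells.reverse()
    return LeastCostPath(
        cells=cells,
        total_cost=float(acc[dest]),
        euclidean_length_m=length,
    )
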