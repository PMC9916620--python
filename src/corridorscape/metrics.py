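"""Summary statistics over collections of least-cost paths.

Four headline metrics describe a scenario's connectivity:

* **total path length** — summed Euclidean length of all paths (km);
  duplicated routes count every time, so it measures route directness;
* **unique path length** — length of the union of distinct path segments
  inside the inner study area (km), counting overlaps once; a measure of
  corridor redundancy/diversity;
* **mean distance to path** — average Euclidean distance from an inner-area
  cell to the nearest path (km); how accessible the corridor network is;
* **mean convergent paths** — average number of distinct paths through an
  inner cell, over cells that carry at least one path; how funnelled
  movement is.

Path overlap is defined on cell-to-cell *moves* (graph edges), not cells:
two paths crossing at a point share no corridor length.  A move belongs to
the inner area when both its endpoint cells do (the midpoint of a move lies
on the shared edge or corner of its two cells).
"""

from __future__ import annotations

from math import sqrt
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cost import LeastCostPath
from .grids import LandCoverGrid

Move = tuple[tuple[int, int], tuple[int, int]]

#: land-cover grouping used for path composition: all crops pooled, the
#: three urban classes pooled.
DEFAULT_ROLE_GROUPS = {
    "crop": "crop",
    "margin": "margin",
    "natural": "natural",
    "grassland": "grassland",
    "urban": "urban",
    "urban_greenspace": "urban",
    "urban_impervious": "urban",
    "bare": "bare",
    "water": "water",
    "other": "other",
}


class MetricsError(ValueError):
    pass


def _canonical_move(a: tuple[int, int], b: tuple[int, int], ncols: int) -> Move:
    return (a, b) if a[0] * ncols + a[1] <= b[0] * ncols + b[1] else (b, a)


def _move_length_m(move: Move, cell_size_m: float) -> float:
    (r1, c1), (r2, c2) = move
    return cell_size_m * (sqrt(2.0) if (r1 != r2 and c1 != c2) else 1.0)


def _check_alignment(paths: Iterable[LeastCostPath], shape: tuple[int, int]) -> None:
    for p in paths:
        for r, c in p.cells:
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise MetricsError(
                    f"path cell {(r, c)} outside grid {shape}; grids misaligned"
                )


def inner_moves(
    paths: Sequence[LeastCostPath], inner_mask: np.ndarray
) -> set[Move]:
    """Canonical set of distinct path moves whose midpoint is inner."""
    _check_alignment(paths, inner_mask.shape)
    ncols = inner_mask.shape[1]
    out: set[Move] = set()
    for p in paths:
        for a, b in p.moves():
            if inner_mask[a] and inner_mask[b]:
                out.add(_canonical_move(a, b, ncols))
    return out


def total_path_length(paths: Sequence[LeastCostPath]) -> float:
    """Summed Euclidean path length in km (duplicates count)."""
    return sum(p.euclidean_length_m for p in paths) / 1000.0


def unique_path_length(
    paths: Sequence[LeastCostPath], inner_mask: np.ndarray, cell_size_m: float
) -> float:
    """Length (km) of the union of distinct inner-area path moves."""
    moves = inner_moves(paths, inner_mask)
    return sum(_move_length_m(m, cell_size_m) for m in moves) / 1000.0


def mean_distance_to_path(
    paths: Sequence[LeastCostPath], inner_mask: np.ndarray, cell_size_m: float
) -> float:
    """Mean Euclidean distance (km) from inner cells to the nearest path.

    Undefined (raises) without any path intersecting the grid — report it
    as missing, not zero.
    """
    if not paths:
        raise MetricsError("mean distance to path is undefined without paths")
    _check_alignment(paths, inner_mask.shape)
    on_path = np.zeros(inner_mask.shape, dtype=bool)
    for p in paths:
        for rc in p.cells:
            on_path[rc] = True
    dist_cells = ndimage.distance_transform_edt(~on_path)
    return float(dist_cells[inner_mask].mean() * cell_size_m / 1000.0)


def mean_convergent_paths(
    paths: Sequence[LeastCostPath], inner_mask: np.ndarray
) -> float:
    """Mean number of distinct paths per inner cell, over inner path cells."""
    _check_alignment(paths, inner_mask.shape)
    counts: dict[tuple[int, int], set[int]] = {}
    for pid, p in enumerate(paths):
        for rc in p.cells:
            if inner_mask[rc]:
                counts.setdefault(rc, set()).add(pid)
    if not counts:
        raise MetricsError("no inner path cells; convergent paths undefined")
    return float(np.mean([len(s) for s in counts.values()]))


# ---------------------------------------------------------------------------
# commonality across resistance levels
# ---------------------------------------------------------------------------


def commonality_across_levels(
    paths_by_level: dict[str, Sequence[LeastCostPath]],
    cell_size_m: float,
    grid_shape: tuple[int, int],
    inner_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Fractions of the path-move union shared by 3 / exactly 2 / 1 levels.

    Length-weighted over the union of canonical moves of the three levels'
    path sets; computed over the full extent unless ``inner_mask`` is given.
    """
    if set(paths_by_level) != {"low", "medium", "high"}:
        raise MetricsError("commonality requires exactly the low/medium/high levels")
    mask = (
        inner_mask
        if inner_mask is not None
        else np.ones(grid_shape, dtype=bool)
    )
    move_sets = {lvl: inner_moves(ps, mask) for lvl, ps in paths_by_level.items()}
    union: set[Move] = set().union(*move_sets.values())
    if not union:
        raise MetricsError("no path moves; commonality undefined")
    lengths = {1: 0.0, 2: 0.0, 3: 0.0}
    for mv in union:
        k = sum(mv in s for s in move_sets.values())
        lengths[k] += _move_length_m(mv, cell_size_m)
    total = sum(lengths.values())
    return {
        "three_levels": lengths[3] / total,
        "two_levels": lengths[2] / total,
        "one_level": lengths[1] / total,
    }


# ---------------------------------------------------------------------------
# land-cover composition
# ---------------------------------------------------------------------------


def landcover_composition(
    paths: Sequence[LeastCostPath],
    landcover: LandCoverGrid,
    role_groups: dict[str, str] | None = None,
) -> pd.Series:
    """Fraction of path length by land-cover group.

    Each move's length is attributed to the group of the cell it *enters*
    (the first cell of a path contributes nothing), so lengths sum exactly
    to the total traversed length.
    """
    _check_alignment(paths, landcover.shape)
    groups = role_groups or DEFAULT_ROLE_GROUPS
    lengths: dict[Hashable, float] = {}
    total = 0.0
    for p in paths:
        for a, b in p.moves():
            code = int(landcover.codes[b])
            role = landcover.class_roles.get(code)
            if role is None or role not in groups:
                raise MetricsError(f"no land-cover group for class code {code}")
            l = _move_length_m((a, b), landcover.cell_size_m)
            lengths[groups[role]] = lengths.get(groups[role], 0.0) + l
            total += l
    if total == 0:
        return pd.Series(dtype=float, name="fraction")
    return pd.Series(
        {g: v / total for g, v in sorted(lengths.items())}, name="fraction"
    )


# ---------------------------------------------------------------------------
# per-iteration aggregation
# ---------------------------------------------------------------------------


def iteration_metrics(
    paths_by_iteration: dict[int, Sequence[LeastCostPath]],
    inner_mask: np.ndarray,
    cell_size_m: float,
) -> pd.DataFrame:
    """The four headline metrics per iteration (one row each).

    Iterations without paths get missing values rather than zeros.
    """
    rows = []
    for it in sorted(paths_by_iteration):
        paths = list(paths_by_iteration[it])
        row: dict[str, float] = {"iteration": it, "n_paths": len(paths)}
        row["total_path_length_km"] = total_path_length(paths)
        row["unique_path_length_inner_km"] = unique_path_length(
            paths, inner_mask, cell_size_m
        )
        try:
            row["mean_distance_to_path_km"] = mean_distance_to_path(
                paths, inner_mask, cell_size_m
            )
        except MetricsError:
            row["mean_distance_to_path_km"] = np.nan
        try:
            row["mean_convergent_paths"] = mean_convergent_paths(paths, inner_mask)
        except MetricsError:
            row["mean_convergent_paths"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("iteration")


def summarize_iterations(per_iteration: pd.DataFrame) -> pd.DataFrame:
    """Append mean and standard-deviation rows across iterations."""
    mean = per_iteration.mean()
    sd = per_iteration.std(ddof=1)
    out = per_iteration.copy()
    out.loc["mean"] = mean
    out.loc["sd"] = sd
    return out
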