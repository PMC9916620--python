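"""The corridor experiment: perimeter points, jitter, pairing, path tracing.

The experiment crosses three agricultural-margin scenarios (restored /
current / none) with three resistance levels (low / medium / high).  For
each of the nine scenarios, source points spaced along the western perimeter
line are paired with destination points on the eastern line within a
Euclidean distance cap, one cost surface is computed per unique source cell,
and the least-cost path to every paired destination is traced.  The whole
procedure is repeated over ``n_iterations`` point sets; the first iteration
uses the original evenly-spaced points, later iterations jitter every point
uniformly within a disc so results do not hinge on exact point placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, Point

from .cost import CostGraph, LeastCostPath, UnreachableError
from .grids import LandCoverGrid, ResistanceGrid, StudyMasks
from .resistance import MARGIN_SCENARIOS, ResistanceTable, scenario_resistance_grid
from .seeding import child_seed_sequence
from .toxload import LEVELS

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the 3x3 margin-scenario x resistance-level design."""

    margin_scenario: str
    level: str

    def __post_init__(self) -> None:
        if self.margin_scenario not in MARGIN_SCENARIOS:
            raise ValueError(f"unknown margin scenario {self.margin_scenario!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown resistance level {self.level!r}")

    @property
    def label(self) -> str:
        return f"{self.margin_scenario}_{self.level}"


ALL_SCENARIOS: tuple[ScenarioSpec, ...] = tuple(
    ScenarioSpec(m, lvl) for m, lvl in product(MARGIN_SCENARIOS, LEVELS)
)


@dataclass(frozen=True)
class RunConfig:
    """Experiment parameters.

    Defaults are the full-valley design (5 km point spacing, 125 km pairing
    cap, 5 km jitter, 20 iterations); :func:`desk_scale_run_config` rescales
    them to the default synthetic landscape.
    """

    point_spacing_m: float = 5_000.0
    max_pair_distance_m: float = 125_000.0
    jitter_radius_m: float = 5_000.0
    n_iterations: int = 20
    master_seed: int = 0
    #: iteration 1 keeps the canonical un-jittered points
    original_first_iteration: bool = True

    def __post_init__(self) -> None:
        if min(self.point_spacing_m, self.max_pair_distance_m) <= 0:
            raise ValueError("distances must be positive")
        if self.jitter_radius_m < 0:
            raise ValueError("jitter radius must be nonnegative")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def desk_scale_run_config(master_seed: int = 0, n_iterations: int = 5) -> RunConfig:
    """Experiment parameters scaled to the 9 km x 6 km default landscape.

    The full-valley design spaces points at 5 km over a ~100 km-wide valley;
    scaling the spacing, jitter radius and pairing cap by the same factor
    (~1/10) preserves the points-per-perimeter and partners-per-point
    structure of the experiment at desk size.
    """
    return RunConfig(
        point_spacing_m=500.0,
        max_pair_distance_m=12_500.0,
        jitter_radius_m=500.0,
        n_iterations=n_iterations,
        master_seed=master_seed,
    )


# ---------------------------------------------------------------------------
# point machinery
# ---------------------------------------------------------------------------


def perimeter_points(line: LineString, spacing_m: float) -> list[Point]:
    """Points along ``line`` at arc-length 0, s, 2s, ... (floor(L/s)+1 total)."""
    if line.length <= 0:
        raise PipelineError("perimeter line has zero length")
    if spacing_m <= 0:
        raise PipelineError("point spacing must be positive")
    n = int(np.floor(line.length / spacing_m)) + 1
    return [line.interpolate(i * spacing_m) for i in range(n)]


def jitter_points(
    points: list[Point],
    radius_m: float,
    seed_seq: np.random.SeedSequence,
    grid: ResistanceGrid | LandCoverGrid | None = None,
    max_tries: int = 100,
) -> list[Point]:
    """Displace each point uniformly within a disc of ``radius_m``.

    Each point has its own child RNG (spawned from ``seed_seq`` by index),
    so jitter is deterministic per (seed, point index) regardless of how
    many rejection draws other points consume.  When ``grid`` is given,
    draws are rejected until the point lands on a valid (non-nodata) cell;
    after ``max_tries`` failures the original point is kept with a warning.
    ``radius_m = 0`` is the identity.
    """
    if radius_m < 0:
        raise PipelineError("jitter radius must be nonnegative")
    if radius_m == 0:
        return list(points)
    out = []
    for rng_seq, pt in zip(seed_seq.spawn(len(points)), points):
        rng = np.random.default_rng(rng_seq)
        chosen = None
        for _ in range(max_tries):
            r = radius_m * np.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            cand = Point(pt.x + r * np.cos(theta), pt.y + r * np.sin(theta))
            if grid is None or _on_valid_cell(cand, grid):
                chosen = cand
                break
        if chosen is None:
            logger.warning(
                "no valid cell within %.0f m of (%.0f, %.0f) after %d draws; "
                "keeping the original point",
                radius_m,
                pt.x,
                pt.y,
                max_tries,
            )
            chosen = pt
        out.append(chosen)
    return out


def point_to_cell(
    pt: Point, shape: tuple[int, int], cell_size_m: float, origin: tuple[float, float]
) -> tuple[int, int]:
    nrows, ncols = shape
    col = int(np.floor((pt.x - origin[0]) / cell_size_m))
    row = int(nrows - 1 - np.floor((pt.y - origin[1]) / cell_size_m))
    return (min(max(row, 0), nrows - 1), min(max(col, 0), ncols - 1))


def _on_valid_cell(pt: Point, grid: ResistanceGrid | LandCoverGrid) -> bool:
    rc = point_to_cell(pt, grid.shape, grid.cell_size_m, grid.origin)
    return bool(grid.valid_mask[rc])


def pair_points(
    west: list[Point], east: list[Point], max_pair_distance_m: float
) -> list[tuple[int, int]]:
    """All (west index, east index) pairs within the Euclidean cap,
    ordered by west index then east index."""
    if not west or not east:
        raise PipelineError("both point lists must be non-empty")
    wxy = np.array([(p.x, p.y) for p in west])
    exy = np.array([(p.x, p.y) for p in east])
    d = cdist(wxy, exy)
    pairs = [(int(i), int(j)) for i, j in np.argwhere(d <= max_pair_distance_m)]
    if not pairs:
        logger.warning("no west-east pairs within %.0f m", max_pair_distance_m)
    return pairs


# ---------------------------------------------------------------------------
# scenario runs
# ---------------------------------------------------------------------------


@dataclass
class ScenarioPaths:
    """All traced paths of one scenario, tagged with full provenance."""

    spec: ScenarioSpec
    paths: list[LeastCostPath]
    n_iterations: int
    resistance: ResistanceGrid
    n_pairs_total: int = 0
    n_unreachable: int = 0

    def by_iteration(self) -> dict[int, list[LeastCostPath]]:
        out: dict[int, list[LeastCostPath]] = {
            i: [] for i in range(1, self.n_iterations + 1)
        }
        for p in self.paths:
            out[p.meta["iteration"]].append(p)
        return out


def run_scenario(
    grid: LandCoverGrid,
    masks: StudyMasks,
    table: ResistanceTable,
    spec: ScenarioSpec,
    config: RunConfig,
) -> ScenarioPaths:
    """Run one scenario: jitter, pair, and trace all least-cost paths.

    Deterministic for a fixed master seed; jitter seeds depend only on the
    iteration and point index, so every scenario sees the same point sets.
    """
    resist = scenario_resistance_grid(grid, table, spec.margin_scenario, spec.level)
    graph = CostGraph(resist.values, cell_size_m=resist.cell_size_m)
    west0 = perimeter_points(masks.west_line, config.point_spacing_m)
    east0 = perimeter_points(masks.east_line, config.point_spacing_m)

    all_paths: list[LeastCostPath] = []
    n_pairs_total = 0
    n_unreachable = 0
    for it in range(1, config.n_iterations + 1):
        if it == 1 and config.original_first_iteration:
            west, east = list(west0), list(east0)
        else:
            west = jitter_points(
                west0,
                config.jitter_radius_m,
                child_seed_sequence(config.master_seed, "jitter_west", it),
                grid=resist,
            )
            east = jitter_points(
                east0,
                config.jitter_radius_m,
                child_seed_sequence(config.master_seed, "jitter_east", it),
                grid=resist,
            )
        pairs = pair_points(west, east, config.max_pair_distance_m)
        n_pairs_total += len(pairs)

        dest_cells = [
            point_to_cell(p, resist.shape, resist.cell_size_m, resist.origin)
            for p in east
        ]
        # one Dijkstra per unique source cell, tracing all its destinations
        by_source: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for wi, ei in pairs:
            src_cell = point_to_cell(
                west[wi], resist.shape, resist.cell_size_m, resist.origin
            )
            by_source.setdefault(src_cell, []).append((wi, ei))
        for src_cell in sorted(by_source):
            surface = graph.cost_distance([src_cell])
            for wi, ei in by_source[src_cell]:
                try:
                    path = surface.trace_path(dest_cells[ei])
                except UnreachableError:
                    n_unreachable += 1
                    logger.warning(
                        "%s it%d: destination %d unreachable from source %d",
                        spec.label,
                        it,
                        ei,
                        wi,
                    )
                    continue
                path.meta = {
                    "source_id": wi,
                    "dest_id": ei,
                    "iteration": it,
                    "margin_scenario": spec.margin_scenario,
                    "level": spec.level,
                    "length_km": path.euclidean_length_m / 1000.0,
                }
                all_paths.append(path)
    logger.info(
        "%s: %d paths from %d pairs over %d iterations (%d unreachable)",
        spec.label,
        len(all_paths),
        n_pairs_total,
        config.n_iterations,
        n_unreachable,
    )
    return ScenarioPaths(
        spec=spec,
        paths=all_paths,
        n_iterations=config.n_iterations,
        resistance=resist,
        n_pairs_total=n_pairs_total,
        n_unreachable=n_unreachable,
    )


def run_all_scenarios(
    grid: LandCoverGrid,
    masks: StudyMasks,
    table: ResistanceTable,
    config: RunConfig,
) -> dict[str, ScenarioPaths]:
    """The full 3x3 factorial; keys are ``<margin>_<level>`` labels."""
    return {
        spec.label: run_scenario(grid, masks, table, spec, config)
        for spec in ALL_SCENARIOS
    }


def paths_to_features(
    paths: list[LeastCostPath],
    shape: tuple[int, int],
    cell_size_m: float,
    origin: tuple[float, float],
):
    """(geometry, properties) pairs for GeoJSON export of traced paths."""
    nrows = shape[0]
    geoms, props = [], []
    for p in paths:
        coords = [
            (
                origin[0] + (c + 0.5) * cell_size_m,
                origin[1] + (nrows - r - 0.5) * cell_size_m,
            )
            for r, c in p.cells
        ]
        if len(coords) == 1:
            coords = coords * 2  # degenerate single-cell path
        geoms.append(LineString(coords))
        props.append({**p.meta, "total_cost": p.total_cost})
    return geoms, props
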