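"""Stage orchestration over persisted artifacts.

Each stage reads only files written by earlier stages, so any stage can be
re-run independently; ``run_all`` chains them into the full workflow
(simulate -> toxic loads -> resistance -> corridors -> metrics) and records
a manifest (parameters, seeds, input digests, artifact inventory) sufficient
to re-run any stage bit-identically.

Artifact inventory (all plain text):

* ``landcover.asc`` / ``inner_mask.asc`` — class-code and mask rasters;
* ``classes.csv`` — code, name, role legend for the land-cover raster;
* ``perimeter_lines.geojson`` — west/east source lines;
* ``pesticide_use.csv`` / ``ld50.csv`` / ``acreage.csv`` — input tables;
* ``toxic_load.csv`` / ``toxic_load_scenarios.csv`` — per-acre loads;
* ``resistance_table.csv`` and ``resist_<margin>_<level>.asc``;
* ``paths_<margin>_<level>.geojson`` — traced least-cost paths;
* ``metrics_<margin>_<level>.csv``, ``metrics_summary.csv``,
  ``composition.csv``, ``commonality.csv``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from . import __version__
from .cost import LeastCostPath
from .grids import LandCoverGrid, StudyMasks
from .gridio import (
    file_digest,
    read_ascii_grid,
    read_geojson,
    write_ascii_grid,
    write_geojson,
    write_manifest,
)
from .metrics import (
    commonality_across_levels,
    iteration_metrics,
    landcover_composition,
    summarize_iterations,
)
from .pipeline import (
    ALL_SCENARIOS,
    RunConfig,
    ScenarioPaths,
    ScenarioSpec,
    paths_to_features,
    point_to_cell,
    run_scenario,
)
from .resistance import (
    ResistanceTable,
    build_resistance_table,
    scenario_resistance_grid,
)
from .synthetic import (
    LandscapeConfig,
    PesticideConfig,
    generate_landscape,
    generate_pesticide_tables,
)
from .toxload import build_toxic_load_table

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def simulate_stage(
    outdir: str | Path,
    seed: int,
    landscape_config: LandscapeConfig | None = None,
    pesticide_config: PesticideConfig | None = None,
) -> tuple[LandCoverGrid, StudyMasks]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lcfg = landscape_config or LandscapeConfig()
    pcfg = pesticide_config or PesticideConfig()
    grid, masks = generate_landscape(lcfg, seed)
    records, ld50s, acreage = generate_pesticide_tables(grid, pcfg, seed)

    write_ascii_grid(
        outdir / "landcover.asc", grid.codes, grid.cell_size_m, grid.origin, grid.nodata_code
    )
    write_ascii_grid(
        outdir / "inner_mask.asc", masks.inner_mask.astype(np.int32), grid.cell_size_m, grid.origin
    )
    pd.DataFrame(
        {
            "code": sorted(grid.class_roles),
            "name": [grid.class_names[c] for c in sorted(grid.class_roles)],
            "role": [grid.class_roles[c] for c in sorted(grid.class_roles)],
        }
    ).to_csv(outdir / "classes.csv", index=False)
    write_geojson(
        outdir / "perimeter_lines.geojson",
        [masks.west_line, masks.east_line],
        [{"side": "west"}, {"side": "east"}],
    )
    records.to_csv(outdir / "pesticide_use.csv", index=False)
    ld50s.rename_axis("chemical").to_csv(outdir / "ld50.csv")
    acreage.rename_axis("land_class").to_csv(outdir / "acreage.csv")
    return grid, masks


def load_landscape(outdir: str | Path) -> tuple[LandCoverGrid, StudyMasks]:
    outdir = Path(outdir)
    codes, cell, origin, nodata = read_ascii_grid(outdir / "landcover.asc")
    legend = pd.read_csv(outdir / "classes.csv")
    grid = LandCoverGrid(
        codes=codes.astype(np.int32),
        cell_size_m=cell,
        origin=origin,
        nodata_code=int(nodata),
        class_roles=dict(zip(legend["code"], legend["role"])),
        class_names=dict(zip(legend["code"], legend["name"])),
    )
    mask_vals, _, _, _ = read_ascii_grid(outdir / "inner_mask.asc")
    geoms, props = read_geojson(outdir / "perimeter_lines.geojson")
    lines = {p["side"]: g for g, p in zip(geoms, props)}
    masks = StudyMasks(
        inner_mask=mask_vals.astype(bool),
        west_line=lines["west"],
        east_line=lines["east"],
    )
    if masks.inner_mask.shape != grid.shape:
        raise ValueError("inner mask and land-cover grids are misaligned")
    return grid, masks


# ---------------------------------------------------------------------------
# toxic load
# ---------------------------------------------------------------------------


def toxload_stage(outdir: str | Path) -> pd.DataFrame:
    outdir = Path(outdir)
    records = pd.read_csv(outdir / "pesticide_use.csv")
    ld50s = pd.read_csv(outdir / "ld50.csv", index_col="chemical")["ld50_ug_per_bee"]
    acreage = pd.read_csv(outdir / "acreage.csv", index_col="land_class")["acres"]
    table = build_toxic_load_table(records, ld50s, acreage)
    table.annual.rename("doses_per_acre").to_csv(outdir / "toxic_load.csv")
    table.scenario.to_csv(outdir / "toxic_load_scenarios.csv")
    return table.scenario


# ---------------------------------------------------------------------------
# resistance
# ---------------------------------------------------------------------------


def resist_stage(
    outdir: str | Path,
    margin_scenarios: tuple[str, ...] = ("restored", "current", "none"),
    levels: tuple[str, ...] = ("low", "medium", "high"),
    overrides: pd.DataFrame | None = None,
) -> ResistanceTable:
    outdir = Path(outdir)
    scenario_loads = pd.read_csv(outdir / "toxic_load_scenarios.csv", index_col="land_class")
    table = build_resistance_table(scenario_loads, overrides=overrides)
    table.to_csv(outdir / "resistance_table.csv")
    grid, _ = load_landscape(outdir)
    for margin in margin_scenarios:
        for level in levels:
            rg = scenario_resistance_grid(grid, table, margin, level)
            write_ascii_grid(
                outdir / f"resist_{margin}_{level}.asc",
                np.where(np.isnan(rg.values), -9999, rg.values),
                rg.cell_size_m,
                rg.origin,
            )
    return table


def load_resistance_table(outdir: str | Path) -> ResistanceTable:
    df = pd.read_csv(Path(outdir) / "resistance_table.csv", index_col="land_class")
    return ResistanceTable(df)


# ---------------------------------------------------------------------------
# corridors
# ---------------------------------------------------------------------------


def corridors_stage(
    outdir: str | Path,
    config: RunConfig,
    scenarios: tuple[ScenarioSpec, ...] = ALL_SCENARIOS,
) -> dict[str, ScenarioPaths]:
    outdir = Path(outdir)
    grid, masks = load_landscape(outdir)
    table = load_resistance_table(outdir)
    results = {}
    for spec in scenarios:
        sp = run_scenario(grid, masks, table, spec, config)
        geoms, props = paths_to_features(
            sp.paths, grid.shape, grid.cell_size_m, grid.origin
        )
        write_geojson(outdir / f"paths_{spec.label}.geojson", geoms, props)
        results[spec.label] = sp
    return results


def load_paths(
    outdir: str | Path, label: str, grid: LandCoverGrid
) -> dict[int, list[LeastCostPath]]:
    """Rebuild traced paths (cells + metadata) from a paths GeoJSON."""
    geoms, props = read_geojson(Path(outdir) / f"paths_{label}.geojson")
    by_iter: dict[int, list[LeastCostPath]] = {}
    for geom, meta in zip(geoms, props):
        cells = [
            point_to_cell(_PointXY(x, y), grid.shape, grid.cell_size_m, grid.origin)
            for x, y in geom.coords
        ]
        deduped = [cells[0]]
        for rc in cells[1:]:
            if rc != deduped[-1]:
                deduped.append(rc)
        length = LineString(geom.coords).length if len(geom.coords) > 1 else 0.0
        path = LeastCostPath(
            cells=deduped,
            total_cost=float(meta.get("total_cost", np.nan)),
            euclidean_length_m=length,
            meta=meta,
        )
        by_iter.setdefault(int(meta["iteration"]), []).append(path)
    return by_iter


class _PointXY:
    __slots__ = ("x", "y")

    def __init__(self, x: float, y: float):
        self.x, self.y = x, y


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def metrics_stage(
    outdir: str | Path,
    n_iterations: int,
    commonality_inner_only: bool = False,
) -> pd.DataFrame:
    outdir = Path(outdir)
    grid, masks = load_landscape(outdir)
    summary_rows = []
    composition_rows = []
    commonality_rows = []
    paths_by_label: dict[str, dict[int, list[LeastCostPath]]] = {}
    for spec in ALL_SCENARIOS:
        by_iter = load_paths(outdir, spec.label, grid)
        for it in range(1, n_iterations + 1):
            by_iter.setdefault(it, [])
        paths_by_label[spec.label] = by_iter
        per_iter = iteration_metrics(by_iter, masks.inner_mask, grid.cell_size_m)
        summarize_iterations(per_iter).to_csv(outdir / f"metrics_{spec.label}.csv")
        mean = per_iter.mean()
        row = {"margin_scenario": spec.margin_scenario, "level": spec.level}
        row.update({k: float(mean[k]) for k in per_iter.columns})
        summary_rows.append(row)
        comp_parts = []
        for it, paths in sorted(by_iter.items()):
            comp = landcover_composition(paths, grid)
            if len(comp):
                comp_parts.append(comp)
        if comp_parts:
            comp_mean = pd.concat(comp_parts, axis=1).fillna(0.0).mean(axis=1)
            for group, frac in comp_mean.items():
                composition_rows.append(
                    {
                        "margin_scenario": spec.margin_scenario,
                        "level": spec.level,
                        "group": group,
                        "fraction": float(frac),
                    }
                )
    for margin in ("restored", "current", "none"):
        fracs: list[dict[str, float]] = []
        for it in range(1, n_iterations + 1):
            by_level = {
                lvl: paths_by_label[f"{margin}_{lvl}"].get(it, [])
                for lvl in ("low", "medium", "high")
            }
            if not any(by_level.values()):
                continue
            fracs.append(
                commonality_across_levels(
                    by_level,
                    grid.cell_size_m,
                    grid.shape,
                    masks.inner_mask if commonality_inner_only else None,
                )
            )
        if fracs:
            mean = pd.DataFrame(fracs).mean()
            commonality_rows.append({"margin_scenario": margin, **mean.to_dict()})

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "metrics_summary.csv", index=False)
    pd.DataFrame(composition_rows).to_csv(outdir / "composition.csv", index=False)
    pd.DataFrame(commonality_rows).to_csv(outdir / "commonality.csv", index=False)
    return summary


# ---------------------------------------------------------------------------
# run-all + manifest
# ---------------------------------------------------------------------------


def run_all(
    outdir: str | Path,
    seed: int,
    landscape_config: LandscapeConfig | None = None,
    pesticide_config: PesticideConfig | None = None,
    run_config: RunConfig | None = None,
) -> pd.DataFrame:
    """Execute the full workflow and write the manifest; returns the
    9-scenario metrics summary."""
    outdir = Path(outdir)
    lcfg = landscape_config or LandscapeConfig()
    pcfg = pesticide_config or PesticideConfig()
    rcfg = run_config or RunConfig(master_seed=seed)
    if rcfg.master_seed != seed:
        rcfg = RunConfig(**{**rcfg.__dict__, "master_seed": seed})
    simulate_stage(outdir, seed, lcfg, pcfg)
    toxload_stage(outdir)
    resist_stage(outdir)
    corridors_stage(outdir, rcfg)
    summary = metrics_stage(outdir, rcfg.n_iterations)
    _write_run_manifest(outdir, seed, lcfg, pcfg, rcfg)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _write_run_manifest(outdir: Path, seed, lcfg, pcfg, rcfg) -> None:
    def cfg_dict(cfg):
        out = {}
        for k, v in cfg.__dict__.items():
            try:
                json.dumps(v)
                out[k] = v
            except TypeError:
                out[k] = repr(v)
        return out

    artifacts = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "software": {"package": "corridorscape", "version": __version__},
        "master_seed": int(seed),
        "seed_derivation": "SeedSequence([master_seed, stage_code, *keys]); "
        "stage codes: landscape=1, pesticide_tables=2, jitter_west=3, jitter_east=4",
        "landscape_config": cfg_dict(lcfg),
        "pesticide_config": {
            "chemicals": [
                {
                    "name": c.name,
                    "ld50_range_ug_per_bee": list(c.ld50_range_ug_per_bee),
                    "base_rate_lbs_per_acre": c.base_rate_lbs_per_acre,
                }
                for c in pcfg.chemicals
            ],
            "years": list(pcfg.years),
            "interannual_cv": pcfg.interannual_cv,
            "class_intensity": pcfg.class_intensity,
        },
        "run_config": cfg_dict(rcfg),
        "artifacts": {name: file_digest(outdir / name) for name in artifacts},
    }
    write_manifest(outdir / "manifest.json", manifest)
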