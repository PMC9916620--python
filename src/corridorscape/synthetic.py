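"""Seeded synthetic agricultural landscapes and pesticide-use tables.

The generator emulates the structure of an intensively farmed valley: an
inner agricultural matrix of rectangular crop parcels, each ringed by a
1-cell agricultural margin (field edges, ditches, uncultivated borders),
with scattered urban patches and water features, surrounded by an outer
perimeter of low-resistance natural/grassland habitat.  Default fractions of
the inner study area mirror the composition of California's Central Valley
core: roughly 65% crops, 9% margins, 10% urban.

Alongside the raster it fabricates the three tables the toxic-load stage
consumes: per-chemical per-year application records with interannual
variation, honey-bee contact LD50 values, and per-class acreage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .grids import LandCoverGrid, StudyMasks
from .seeding import child_rng

logger = logging.getLogger(__name__)

# 1 m^2 = 1/4046.8564224 acre, so a 30 m cell is 0.2223948 acre.
ACRES_PER_SQUARE_METER = 1.0 / 4046.8564224

# land-cover class codes
CODE_NATURAL = 1
CODE_GRASSLAND = 2
CODE_MARGIN = 3
CODE_URBAN = 4
CODE_URBAN_GREENSPACE = 5
CODE_URBAN_IMPERVIOUS = 6
CODE_WATER = 7
CODE_BARE = 8
CROP_CODE_BASE = 10

NON_CROP_ROLES = {
    CODE_NATURAL: "natural",
    CODE_GRASSLAND: "grassland",
    CODE_MARGIN: "margin",
    CODE_URBAN: "urban",
    CODE_URBAN_GREENSPACE: "urban_greenspace",
    CODE_URBAN_IMPERVIOUS: "urban_impervious",
    CODE_WATER: "water",
    CODE_BARE: "bare",
}
NON_CROP_NAMES = {
    CODE_NATURAL: "natural",
    CODE_GRASSLAND: "grassland",
    CODE_MARGIN: "agricultural_margin",
    CODE_URBAN: "urban",
    CODE_URBAN_GREENSPACE: "urban_greenspace",
    CODE_URBAN_IMPERVIOUS: "urban_impervious",
    CODE_WATER: "water",
    CODE_BARE: "bare_soil",
}

#: Default crop list.  ``intensity`` is the crop's mean pesticide application
#: rate relative to the urban baseline; under linear load-to-resistance
#: scaling with urban anchor 8 it sets the expected mid-scenario resistance
#: (e.g. intensity 4.0 -> resistance ~32, the almond-orchard regime).
DEFAULT_CROPS: tuple[tuple[str, float], ...] = (
    ("rice", 0.125),
    ("corn", 0.625),
    ("wheat", 0.75),
    ("alfalfa", 2.5),
    ("tomatoes", 3.625),
    ("almonds", 4.0),
    ("citrus", 11.5),
)


class LandscapeSizingError(ValueError):
    """Grid too small to host the requested parcels."""


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    The default 300x200 grid of 30 m cells (9 km x 6 km) keeps the full
    nine-scenario corridor experiment desk-sized while preserving the
    parcel/margin/urban geometry of the real valley floor.
    """

    nrows: int = 200
    ncols: int = 300
    cell_size_m: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_code: int = -9999
    outer_ring_width: int = 15
    margin_width: int = 1
    n_parcels: int = 60
    parcel_side_range: tuple[int, int] = (26, 34)
    crop_fraction: float = 0.65
    margin_fraction: float = 0.09  # realized by parcel geometry, not a dial
    urban_fraction: float = 0.10
    water_fraction: float = 0.01
    natural_fraction: float = 0.04
    urban_patch_count: int = 6
    natural_patch_count: int = 4
    water_patch_count: int = 3
    crops: tuple[tuple[str, float], ...] = DEFAULT_CROPS

    def crop_codes(self) -> dict[int, str]:
        return {CROP_CODE_BASE + i: name for i, (name, _) in enumerate(self.crops)}

    def crop_intensities(self) -> dict[str, float]:
        return dict(self.crops)


@dataclass(frozen=True)
class ChemicalSpec:
    """One active ingredient: contact LD50 range (µg/bee) and the mean
    application rate on the urban baseline class (lbs/acre/year)."""

    name: str
    ld50_range_ug_per_bee: tuple[float, float]
    base_rate_lbs_per_acre: float


#: Moderately-to-highly bee-toxic actives with realistic contact LD50s.
DEFAULT_CHEMICALS: tuple[ChemicalSpec, ...] = (
    ChemicalSpec("spinosad", (0.0029, 0.0029), 0.0047),
    ChemicalSpec("imidacloprid", (0.03, 0.09), 0.010),
    ChemicalSpec("chlorpyrifos", (0.05, 0.07), 0.020),
    ChemicalSpec("lambda-cyhalothrin", (0.02, 0.05), 0.002),
    ChemicalSpec("carbaryl", (0.85, 1.30), 0.050),
    ChemicalSpec("malathion", (0.16, 0.27), 0.030),
)


@dataclass(frozen=True)
class PesticideConfig:
    chemicals: tuple[ChemicalSpec, ...] = DEFAULT_CHEMICALS
    years: tuple[int, ...] = (2014, 2015, 2016)
    interannual_cv: float = 0.3
    #: extra per-class multipliers; crop intensities come from the landscape
    #: config, urban defaults to 1.0 (the anchor class).
    class_intensity: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# landscape generation
# ---------------------------------------------------------------------------


def generate_landscape(
    config: LandscapeConfig = LandscapeConfig(), seed: int = 0
) -> tuple[LandCoverGrid, StudyMasks]:
    """Generate a synthetic land-cover grid and its study masks.

    Deterministic for a given ``(config, seed)``.  Crop parcels are placed
    in greedy row bands, each proposal accepted only if the parcel plus its
    margin ring avoids urban/water patches and earlier parcels; placement
    stops when the inner crop fraction reaches its target or ``n_parcels``
    parcels are down.
    """
    rng = child_rng(seed, "landscape")
    nrows, ncols, ring = config.nrows, config.ncols, config.outer_ring_width
    mw = config.margin_width
    if nrows < 2 or ncols < 2:
        raise LandscapeSizingError("grid must be at least 2x2")
    inner = (ring, nrows - ring, ring, ncols - ring)
    ir0, ir1, ic0, ic1 = inner
    if ir1 - ir0 < config.parcel_side_range[0] + 2 * mw or ic1 - ic0 < config.parcel_side_range[0] + 2 * mw:
        raise LandscapeSizingError(
            "inner area too small for the requested parcel size; "
            "shrink parcels or the outer ring"
        )

    codes = np.full((nrows, ncols), CODE_GRASSLAND, dtype=np.int32)
    # outer perimeter: grassland with a natural outermost band
    natural_band = max(1, ring // 2)
    codes[:natural_band, :] = CODE_NATURAL
    codes[-natural_band:, :] = CODE_NATURAL
    codes[:, :natural_band] = CODE_NATURAL
    codes[:, -natural_band:] = CODE_NATURAL

    inner_cells = (ir1 - ir0) * (ic1 - ic0)

    # Everything structured — crop parcels, urban blocks, water bodies,
    # natural patches — is laid out in the same greedy row-band scan so the
    # inner matrix packs as densely as a real farmed valley floor.  Each
    # land use draws from an area quota; crop parcels additionally get a
    # margin ring and count toward n_parcels.
    quota = {
        "crop": config.crop_fraction * inner_cells,
        "urban": config.urban_fraction * inner_cells if config.urban_patch_count else 0.0,
        "water": config.water_fraction * inner_cells if config.water_patch_count else 0.0,
        "natural": config.natural_fraction * inner_cells if config.natural_patch_count else 0.0,
    }
    remaining = dict(quota)
    crop_codes = list(config.crop_codes())
    smin, smax = config.parcel_side_range
    crop_cells = 0
    n_placed = 0
    parcel_mask = np.zeros_like(codes, dtype=bool)
    margin_mask = np.zeros_like(codes, dtype=bool)
    occupied = np.zeros_like(codes, dtype=bool)

    def place_noncrop(kind: str, y: int, x: int, band_h: int) -> int:
        count = {
            "urban": config.urban_patch_count,
            "water": config.water_patch_count,
            "natural": config.natural_patch_count,
        }[kind]
        patch_cells = max(quota[kind] / max(count, 1), 9.0)
        w = int(np.clip(round(patch_cells / band_h), 3, ic1 - mw - x))
        if w < 3:
            return 0
        blk = (slice(y, y + band_h), slice(x, x + w))
        if kind == "urban":
            codes[blk] = CODE_URBAN
            gh, gw = max(1, band_h // 3), max(1, w // 3)
            codes[y : y + gh, x : x + gw] = CODE_URBAN_GREENSPACE
            codes[y + band_h - gh : y + band_h, x + w - gw : x + w] = CODE_URBAN_IMPERVIOUS
        elif kind == "water":
            codes[blk] = CODE_WATER
        else:
            codes[blk] = CODE_NATURAL
        occupied[blk] = True
        remaining[kind] -= band_h * w
        return w

    y = ir0 + mw
    while y + smin <= ir1 - mw:
        band_h = min(int(rng.integers(smin, smax + 1)), ir1 - mw - y)
        if band_h < smin:
            break
        x = ic0 + mw
        while x + 3 <= ic1 - mw:
            kinds = [k for k, v in remaining.items() if v > 0]
            if "crop" in kinds and n_placed >= config.n_parcels:
                kinds.remove("crop")
            if not kinds:
                break
            weights = np.array([remaining[k] for k in kinds])
            kind = kinds[int(rng.choice(len(kinds), p=weights / weights.sum()))]
            if kind == "crop":
                w = min(int(rng.integers(smin, smax + 1)), ic1 - mw - x)
                if w < smin:
                    break
                blk = (slice(y - mw, y + band_h + mw), slice(x - mw, x + w + mw))
                if occupied[blk].any() or parcel_mask[blk].any():
                    x += 2
                    continue
                codes[y : y + band_h, x : x + w] = int(rng.choice(crop_codes))
                parcel_mask[y : y + band_h, x : x + w] = True
                ringblk = np.zeros_like(codes, dtype=bool)
                ringblk[blk] = True
                ringblk[y : y + band_h, x : x + w] = False
                margin_mask |= ringblk
                crop_cells += band_h * w
                remaining["crop"] -= band_h * w
                n_placed += 1
                x += w + 2 * mw + int(rng.integers(0, 2))
            else:
                w = place_noncrop(kind, y, x, band_h)
                if w == 0:
                    break
                x += w + mw + int(rng.integers(0, 2))
        y += band_h + 2 * mw + int(rng.integers(0, 2))

    if config.n_parcels > 0 and n_placed == 0:
        raise LandscapeSizingError("could not place any crop parcel on this grid")

    margin_mask &= ~parcel_mask & ~occupied
    codes[margin_mask] = CODE_MARGIN

    class_roles = dict(NON_CROP_ROLES)
    class_names = dict(NON_CROP_NAMES)
    for code, name in config.crop_codes().items():
        class_roles[code] = "crop"
        class_names[code] = name

    grid = LandCoverGrid(
        codes=codes,
        cell_size_m=config.cell_size_m,
        origin=config.origin,
        nodata_code=config.nodata_code,
        class_roles=class_roles,
        class_names=class_names,
    )

    inner_mask = np.zeros((nrows, ncols), dtype=bool)
    inner_mask[ir0:ir1, ic0:ic1] = True
    cell = config.cell_size_m
    ox, oy = config.origin
    x_west = ox + (ring - 0.5) * cell
    x_east = ox + (ncols - ring + 0.5) * cell
    y_lo = oy + ring * cell
    y_hi = oy + (nrows - ring) * cell
    masks = StudyMasks(
        inner_mask=inner_mask,
        west_line=LineString([(x_west, y_lo), (x_west, y_hi)]),
        east_line=LineString([(x_east, y_lo), (x_east, y_hi)]),
    )
    grid.validate()
    masks.validate(grid)

    realized = crop_cells / inner_cells
    logger.info(
        "landscape: %d parcels, inner fractions crop=%.3f margin=%.3f urban=%.3f",
        n_placed,
        realized,
        (margin_mask & inner_mask).sum() / inner_cells,
        (grid.role_mask("urban", "urban_greenspace", "urban_impervious") & inner_mask).sum()
        / inner_cells,
    )
    return grid, masks


# ---------------------------------------------------------------------------
# pesticide tables
# ---------------------------------------------------------------------------


def class_acreage(grid: LandCoverGrid) -> pd.Series:
    """Acres per load-bearing land class (crops, plus the three urban
    classes pooled as ``urban`` the way coarse urban land-cover maps report
    them)."""
    acre_per_cell = grid.cell_size_m**2 * ACRES_PER_SQUARE_METER
    out: dict[str, float] = {}
    for code in grid.codes_with_role("crop"):
        n = int((grid.codes == code).sum())
        if n:
            out[grid.class_names[code]] = n * acre_per_cell
    n_urban = int(grid.role_mask("urban", "urban_greenspace", "urban_impervious").sum())
    if n_urban:
        out["urban"] = n_urban * acre_per_cell
    return pd.Series(out, name="acres")


def generate_pesticide_tables(
    grid: LandCoverGrid,
    config: PesticideConfig = PesticideConfig(),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Fabricate application records, LD50s, and acreage for ``grid``.

    Returns ``(use_records, ld50s, acreage)``:

    * ``use_records`` — DataFrame ``chemical, land_class, year, pounds`` with
      one record per (class, chemical, year);
    * ``ld50s`` — Series chemical -> contact LD50 (µg/bee), drawn
      log-uniformly from each chemical's configured range;
    * ``acreage`` — Series land class -> acres, derived from the grid.

    Interannual variation is lognormal with the configured coefficient of
    variation; ``cv=0`` reproduces identical pounds in all years.
    """
    if not config.chemicals:
        raise ConfigurationError("chemical list is empty")
    if len(config.years) != len(set(config.years)):
        raise ConfigurationError("years must be distinct")
    rng = child_rng(seed, "pesticide_tables")

    acreage = class_acreage(grid)
    crop_intensity = {
        grid.class_names[code]: _intensity_for(grid.class_names[code])
        for code in grid.codes_with_role("crop")
    }
    intensity = {**crop_intensity, "urban": 1.0, **config.class_intensity}

    ld50s = pd.Series(
        {
            chem.name: float(
                np.exp(
                    rng.uniform(
                        np.log(chem.ld50_range_ug_per_bee[0]),
                        np.log(chem.ld50_range_ug_per_bee[1]),
                    )
                )
            )
            for chem in config.chemicals
        },
        name="ld50_ug_per_bee",
    )

    cv = config.interannual_cv
    sigma = float(np.sqrt(np.log1p(cv**2)))
    rows = []
    for land_class in acreage.index:
        if land_class not in intensity:
            continue
        acres = float(acreage[land_class])
        for chem in config.chemicals:
            mean_rate = chem.base_rate_lbs_per_acre * intensity[land_class]
            for year in config.years:
                factor = 1.0 if cv == 0 else float(np.exp(rng.normal(-sigma**2 / 2, sigma)))
                rows.append(
                    {
                        "chemical": chem.name,
                        "land_class": land_class,
                        "year": int(year),
                        "pounds": acres * mean_rate * factor,
                    }
                )
    records = pd.DataFrame(rows, columns=["chemical", "land_class", "year", "pounds"])
    return records, ld50s, acreage


def _intensity_for(crop_name: str) -> float:
    for name, intensity in DEFAULT_CROPS:
        if name == crop_name:
            return intensity
    return 1.0


def desk_scale_config() -> LandscapeConfig:
    """The default desk-scale study landscape (alias for the defaults)."""
    return LandscapeConfig()


def single_parcel_config(
    grid_size: int = 20, parcel_side: int = 10, ring: int = 4
) -> LandscapeConfig:
    """A minimal one-parcel configuration, handy for worked examples."""
    return replace(
        LandscapeConfig(),
        nrows=grid_size,
        ncols=grid_size,
        outer_ring_width=ring,
        n_parcels=1,
        parcel_side_range=(parcel_side, parcel_side),
        urban_patch_count=0,
        water_patch_count=0,
        natural_patch_count=0,
        crop_fraction=1.0,
    )
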