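"""Core raster containers: land-cover grids, study masks, resistance grids.

Conventions used throughout the package:

* grids are row-major 2-D numpy arrays; cell (0, 0) is the top-left cell;
* ``origin`` is the (x, y) coordinate of the *lower-left* corner of the grid
  in a projected CRS with meter units (the ESRI ASCII ``xllcorner`` /
  ``yllcorner`` convention);
* the center of cell (row, col) is at
  ``(origin_x + (col + 0.5) * cell, origin_y + (nrows - row - 0.5) * cell)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

#: Recognized land-cover roles.  ``crop`` cells additionally carry a crop
#: name through :attr:`LandCoverGrid.class_names`.
ROLES = frozenset(
    {
        "crop",
        "margin",
        "natural",
        "grassland",
        "urban",
        "urban_greenspace",
        "urban_impervious",
        "bare",
        "water",
        "other",
    }
)


class GridValidationError(ValueError):
    """A grid violates one of its structural invariants."""


@dataclass
class LandCoverGrid:
    """Integer class-code raster plus the semantics of its codes.

    Parameters
    ----------
    codes
        2-D integer array of land-cover class codes.
    cell_size_m
        Edge length of a (square) cell, meters.
    origin
        (x, y) of the lower-left grid corner in a projected, meter-unit CRS.
    nodata_code
        Code marking cells outside the valid extent.
    class_roles
        Map class code -> role (one of :data:`ROLES`).
    class_names
        Map class code -> human-readable class name (crop name for crops).
    """

    codes: np.ndarray
    cell_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_code: int = -9999
    class_roles: dict[int, str] = field(default_factory=dict)
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2 or min(self.codes.shape) < 2:
            raise GridValidationError("land-cover grid must be 2-D, at least 2x2")
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise GridValidationError("land-cover codes must be integers")
        if self.cell_size_m <= 0:
            raise GridValidationError("cell_size_m must be positive")
        for code, role in self.class_roles.items():
            if role not in ROLES:
                raise GridValidationError(f"unknown role {role!r} for code {code}")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != self.nodata_code

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrows = self.codes.shape[0]
        x = self.origin[0] + (col + 0.5) * self.cell_size_m
        y = self.origin[1] + (nrows - row - 0.5) * self.cell_size_m
        return (x, y)

    def cell_at(self, x: float, y: float) -> tuple[int, int]:
        """Cell (row, col) containing point (x, y); clipped to the grid."""
        nrows, ncols = self.codes.shape
        col = int(np.floor((x - self.origin[0]) / self.cell_size_m))
        row = int(nrows - 1 - np.floor((y - self.origin[1]) / self.cell_size_m))
        return (min(max(row, 0), nrows - 1), min(max(col, 0), ncols - 1))

    # -- semantics ------------------------------------------------------
    def codes_with_role(self, *roles: str) -> list[int]:
        return sorted(c for c, r in self.class_roles.items() if r in roles)

    def role_mask(self, *roles: str) -> np.ndarray:
        wanted = self.codes_with_role(*roles)
        return np.isin(self.codes, wanted)

    def validate(self) -> None:
        """Check the cross-field invariants; raise on violation."""
        present = np.unique(self.codes[self.valid_mask])
        missing = [int(c) for c in present if int(c) not in self.class_roles]
        if missing:
            raise GridValidationError(f"codes without a declared role: {missing}")
        margin = self.role_mask("margin")
        if margin.any():
            crop = self.role_mask("crop")
            near_crop = _binary_dilate8(crop)
            orphans = margin & ~near_crop
            if orphans.any():
                n = int(orphans.sum())
                raise GridValidationError(
                    f"{n} margin cell(s) have no 8-neighbouring crop cell"
                )

    def copy(self) -> "LandCoverGrid":
        return LandCoverGrid(
            codes=self.codes.copy(),
            cell_size_m=self.cell_size_m,
            origin=self.origin,
            nodata_code=self.nodata_code,
            class_roles=dict(self.class_roles),
            class_names=dict(self.class_names),
        )


def _binary_dilate8(mask: np.ndarray) -> np.ndarray:
    """8-neighbourhood binary dilation (keeps the original cells)."""
    out = mask.copy()
    out[:-1, :] |= mask[1:, :]
    out[1:, :] |= mask[:-1, :]
    out[:, :-1] |= mask[:, 1:]
    out[:, 1:] |= mask[:, :-1]
    out[:-1, :-1] |= mask[1:, 1:]
    out[1:, 1:] |= mask[:-1, :-1]
    out[:-1, 1:] |= mask[1:, :-1]
    out[1:, :-1] |= mask[:-1, 1:]
    return out


@dataclass
class StudyMasks:
    """Inner (agricultural core) mask and the two perimeter source lines."""

    inner_mask: np.ndarray
    west_line: LineString
    east_line: LineString

    def validate(self, grid: LandCoverGrid) -> None:
        if self.inner_mask.shape != grid.shape:
            raise GridValidationError("inner_mask shape differs from land-cover grid")
        if (self.inner_mask & ~grid.valid_mask).any():
            raise GridValidationError("inner_mask extends onto nodata cells")
        if self.west_line.intersects(self.east_line):
            raise GridValidationError("west and east perimeter lines intersect")


@dataclass
class ResistanceGrid:
    """Per-cell resistance to movement aligned to a :class:`LandCoverGrid`.

    Resistance 1 is the isolation-by-distance baseline; 100 means a cell is
    100 times harder to traverse.  Nodata cells are impassable and stored as
    ``nan``.
    """

    values: np.ndarray
    cell_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    margin_scenario: str = "current"
    level: str = "medium"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        valid = ~np.isnan(self.values)
        if valid.any():
            vmin, vmax = self.values[valid].min(), self.values[valid].max()
            if vmin < 1 or vmax > 100:
                raise GridValidationError(
                    f"resistance values outside [1, 100]: min={vmin}, max={vmax}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def label(self) -> str:
        return f"{self.margin_scenario}_{self.level}"
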