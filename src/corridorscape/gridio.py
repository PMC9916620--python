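"""Readers and writers for the package's on-disk formats.

Rasters are exchanged as ESRI ASCII grids (``.asc``) — a plain-text header
(``ncols``/``nrows``/``xllcorner``/``yllcorner``/``cellsize``/
``NODATA_value``) followed by row-major cell values.  Grids are assumed to be
in a projected CRS with meter units; the ASCII format carries no CRS tag, so
a cell size below 0.01 (which would mean sub-centimeter cells and in practice
indicates degree units) is rejected as an unsupported geographic CRS.

Vector data (least-cost paths, perimeter lines) are exchanged as GeoJSON
FeatureCollections.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
from shapely.geometry import mapping, shape

_MIN_PROJECTED_CELLSIZE = 0.01


class UnsupportedCRSError(ValueError):
    """Raster appears to be in a geographic (degree) CRS."""


class RasterFormatError(ValueError):
    """Malformed ESRI ASCII grid."""


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    cell_size_m: float,
    origin: tuple[float, float] = (0.0, 0.0),
    nodata: float = -9999,
) -> Path:
    """Write a 2-D array as an ESRI ASCII grid.

    ``nan`` cells (for float grids) are written as the nodata value.  Integer
    arrays are written without decimal points so they round-trip exactly.
    """
    path = Path(path)
    values = np.asarray(values)
    if values.ndim != 2:
        raise RasterFormatError("raster must be 2-D")
    if cell_size_m < _MIN_PROJECTED_CELLSIZE:
        raise UnsupportedCRSError(
            f"cell size {cell_size_m} looks like degrees; projected meter CRS required"
        )
    nrows, ncols = values.shape
    is_int = np.issubdtype(values.dtype, np.integer)
    out = values
    if not is_int:
        out = values.copy()
        out[np.isnan(out)] = nodata
        if np.all(out == np.floor(out)) and np.all(np.abs(out) < 2**53):
            out = out.astype(np.int64)
            is_int = True
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {origin[0]!r}\n"
        f"yllcorner {origin[1]!r}\n"
        f"cellsize {cell_size_m!r}\n"
        f"NODATA_value {int(nodata) if is_int else nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        fmt = "%d" if is_int else "%.17g"
        np.savetxt(fh, out, fmt=fmt, delimiter=" ")
    return path


def read_ascii_grid(
    path: str | Path,
) -> tuple[np.ndarray, float, tuple[float, float], float]:
    """Read an ESRI ASCII grid.

    Returns ``(values, cell_size_m, origin, nodata)``.  Values are int64 when
    every cell (including nodata) is integral, else float64 with nodata kept
    as its sentinel value (not converted to nan — conversion is the caller's
    choice).
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols",
            "nrows",
            "xllcorner",
            "yllcorner",
            "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"missing header field {key!r} in {path}")
    if "nodata_value" not in header:
        import warnings

        warnings.warn(f"{path}: no NODATA_value tag; assuming -9999", stacklevel=2)
        header["nodata_value"] = -9999.0
    cell = header["cellsize"]
    if cell < _MIN_PROJECTED_CELLSIZE:
        raise UnsupportedCRSError(
            f"{path}: cell size {cell} looks like degrees; projected meter CRS required"
        )
    values = np.loadtxt(lines[data_start:], ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise RasterFormatError(
            f"{path}: data shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    if np.all(values == np.floor(values)) and np.all(np.abs(values) < 2**53):
        values = values.astype(np.int64)
    origin = (header["xllcorner"], header["yllcorner"])
    return values, cell, origin, header["nodata_value"]


# -- GeoJSON -----------------------------------------------------------------


def write_geojson(
    path: str | Path,
    geometries: Iterable[Any],
    properties: Iterable[dict[str, Any]] | None = None,
) -> Path:
    """Write shapely geometries (+ per-feature properties) as GeoJSON."""
    path = Path(path)
    geometries = list(geometries)
    props = list(properties) if properties is not None else [{} for _ in geometries]
    if len(props) != len(geometries):
        raise ValueError("properties and geometries differ in length")
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": p}
        for geom, p in zip(geometries, props)
    ]
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=None, separators=(",", ":"), sort_keys=True)
        fh.write("\n")
    return path


def read_geojson(path: str | Path) -> tuple[list[Any], list[dict[str, Any]]]:
    """Read a GeoJSON FeatureCollection into (shapely geometries, properties)."""
    with open(path) as fh:
        doc = json.load(fh)
    geoms, props = [], []
    for feat in doc.get("features", []):
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties") or {})
    return geoms, props


# -- manifest ----------------------------------------------------------------


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, manifest: dict[str, Any]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
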