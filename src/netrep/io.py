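"""Raster and vector file I/O.

Two raster dialects are supported behind one pair of functions:

* the ESRI ASCII grid text layout (``.asc`` / ``.csv`` / ``.txt``): a 6-line
  header (ncols, nrows, xllcorner, yllcorner, cellsize, nodata_value)
  followed by rows of values, row 0 northernmost — the portable,
  diff-friendly format used throughout the test-suite and examples;
* single-band TIFF (``.tif`` / ``.tiff``) via :mod:`tifffile`, with the cell
  geometry, CRS label and nodata value carried as JSON in the
  ImageDescription tag.

Vector site networks travel as GeoJSON (points or polygons with a ``site``
property); class tables as YAML mappings code -> name.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .grid import CategoricalGrid, Grid, Transform

_ASCII_SUFFIXES = {".asc", ".csv", ".txt"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


class GridLoadError(ValueError):
    """Raised when a raster file cannot be loaded as a valid grid."""


def _check_finite(values: np.ndarray, valid: np.ndarray, path: Path) -> None:
    bad = valid & ~np.isfinite(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise GridLoadError(
            f"{path}: non-finite value at valid cell (row={r}, col={c})")


def _read_ascii(path: Path) -> tuple[np.ndarray, Transform, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            header[key.lower()] = float(val)
        body = fh.read()
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    values = np.array(body.replace(",", " ").split(), dtype=float)
    if values.size != nrows * ncols:
        raise GridLoadError(
            f"{path}: expected {nrows * ncols} values, found {values.size}")
    values = values.reshape(nrows, ncols)
    transform = Transform(header["xllcorner"],
                          header["yllcorner"] + nrows * cell, cell, cell)
    return values, transform, nodata


def _write_ascii(path: Path, values: np.ndarray, transform: Transform,
                 nodata: float, fmt: str) -> None:
    if not np.isclose(transform.cell_width, transform.cell_height):
        raise ValueError("ASCII grid requires square cells")
    nrows, ncols = values.shape
    yll = transform.y_origin - nrows * transform.cell_height
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(transform.x_origin)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(transform.cell_width)!r}\n")
        fh.write(f"nodata_value {float(nodata)!r}\n")
        for row in values:
            fh.write(" ".join(fmt % float(v) for v in row))
            fh.write("\n")


def _read_tiff(path: Path) -> tuple[np.ndarray, Transform, float, str]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise GridLoadError(f"{path}: multi-band TIFF not supported "
                                f"({len(tif.pages)} pages)")
        page = tif.pages[0]
        arr = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    if arr.ndim != 2:
        raise GridLoadError(f"{path}: expected a single band, got shape {arr.shape}")
    t = meta.get("transform", [0.0, float(arr.shape[0]), 1.0, 1.0])
    transform = Transform(*t)
    return arr, transform, meta.get("nodata", -9999.0), meta.get("crs", "")


def _write_tiff(path: Path, values: np.ndarray, transform: Transform,
                nodata: float, crs_label: str) -> None:
    import tifffile

    meta = {"transform": [transform.x_origin, transform.y_origin,
                          transform.cell_width, transform.cell_height],
            "nodata": nodata, "crs": crs_label}
    tifffile.imwrite(path, values, description=json.dumps(meta))


def read_grid(path: str | Path) -> Grid:
    """Read a continuous single-band raster.

    Nodata cells become invalid; valid cells must be finite or a
    :class:`GridLoadError` naming the offending cell is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    crs = ""
    if path.suffix.lower() in _TIFF_SUFFIXES:
        values, transform, nodata, crs = _read_tiff(path)
        values = values.astype(float)
    elif path.suffix.lower() in _ASCII_SUFFIXES:
        values, transform, nodata = _read_ascii(path)
    else:
        raise GridLoadError(f"{path}: unrecognised raster suffix {path.suffix!r}")
    valid = ~np.isclose(values, nodata, rtol=0, atol=0, equal_nan=True)
    valid &= ~np.isnan(values)
    _check_finite(values, valid, path)
    return Grid(values, valid, transform, crs_label=crs, nodata=nodata)


def write_grid(path: str | Path, grid: Grid, fmt: str = "%r") -> None:
    """Write a continuous grid (dialect chosen by suffix).

    The default ``%r`` float format makes the ASCII dialect round-trip
    bit-exactly.
    """
    path = Path(path)
    values = grid.filled()
    if path.suffix.lower() in _TIFF_SUFFIXES:
        _write_tiff(path, values.astype(np.float32), grid.transform,
                    grid.nodata, grid.crs_label)
    else:
        _write_ascii(path, values, grid.transform, grid.nodata, fmt)


def read_categorical_grid(path: str | Path,
                          class_table: dict[int, str] | str | Path) -> CategoricalGrid:
    """Read a categorical raster plus its code -> class-name table.

    *class_table* may be a mapping or a path to a YAML file of one.
    """
    if not isinstance(class_table, dict):
        class_table = read_class_table(class_table)
    g = read_grid(path)
    codes = np.rint(g.values).astype(np.int64)
    if g.valid.any() and not np.allclose(g.values[g.valid], codes[g.valid]):
        raise GridLoadError(f"{path}: non-integer codes in categorical raster")
    codes[~g.valid] = 0
    return CategoricalGrid(codes, dict(class_table), g.valid, g.transform,
                           g.crs_label, nodata_code=int(g.nodata))


def write_categorical_grid(path: str | Path, cat: CategoricalGrid,
                           class_table_path: str | Path | None = None) -> None:
    codes = cat.codes.astype(float)
    codes[~cat.valid] = float(cat.nodata_code)
    g = Grid(codes, cat.valid, cat.transform, cat.crs_label,
             nodata=float(cat.nodata_code))
    write_grid(path, g, fmt="%d")
    if class_table_path is not None:
        write_class_table(class_table_path, cat.class_table)


def read_class_table(path: str | Path) -> dict[int, str]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {int(k): str(v) for k, v in raw.items()}


def write_class_table(path: str | Path, table: dict[int, str]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({int(k): str(v) for k, v in table.items()}, fh)


def read_features(path: str | Path) -> list[dict]:
    """Read GeoJSON features as a list of {'geometry': ..., 'properties': ...}."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        return doc["features"]
    if doc.get("type") == "Feature":
        return [doc]
    raise ValueError(f"{path}: not a GeoJSON Feature or FeatureCollection")


def write_features(path: str | Path, features: list[dict]) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
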