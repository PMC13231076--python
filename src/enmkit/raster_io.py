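"""Raster and point-table file I/O.

Two raster formats are supported:

* **ESRI ASCII grid** (``.asc``/``.txt``) — the plain-text exchange format
  with the six-field header ``ncols nrows xllcorner yllcorner cellsize
  NODATA_value``. Values are written with six significant digits.
* **GeoTIFF** (``.tif``/``.tiff``) — single-band float64 TIFF with the
  standard geo tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA) so that
  GIS software places the grid correctly. Written via :mod:`tifffile`.

There is deliberately **no resampling**: layers read into one stack must
already share a grid, and a mismatch raises :class:`AlignmentError` naming
the offending file. Pre-alignment belongs in the GIS step that produced the
layers.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import AlignmentError, ConfigError
from .grid import GridSpec
from .raster import PredictorStack

__all__ = [
    "read_ascii_grid", "write_ascii_grid", "read_geotiff", "write_geotiff",
    "read_raster", "write_raster", "read_stack", "write_stack",
    "read_points", "write_points",
]

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str | os.PathLike) -> tuple[GridSpec, np.ndarray]:
    """Read one ESRI ASCII grid; nodata cells come back as NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(0)
        skip = len(header)
        data = np.loadtxt(fh, skiprows=skip, dtype=float)
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= set(header):
        raise ConfigError(f"{path}: incomplete ASCII grid header, found {sorted(header)}")
    nodata = header.get("nodata_value", -9999.0)
    grid = GridSpec(
        nrows=int(header["nrows"]), ncols=int(header["ncols"]),
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"], origin_y=header["yllcorner"],
        nodata=nodata,
    )
    data = np.atleast_2d(data)
    if data.shape != grid.shape:
        raise ConfigError(f"{path}: data block {data.shape} does not match header {grid.shape}")
    data[data == nodata] = np.nan
    return grid, data


def write_ascii_grid(path: str | os.PathLike, grid: GridSpec, data: np.ndarray) -> None:
    """Write one layer as an ESRI ASCII grid (6 significant digits)."""
    data = np.asarray(data, dtype=float)
    if data.shape != grid.shape:
        raise AlignmentError(f"data shape {data.shape} != grid {grid.shape}")
    out = np.where(np.isnan(data), grid.nodata, data)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin_x:.10g}\n")
        fh.write(f"yllcorner {grid.origin_y:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata:.10g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# GeoTIFF (single band, float64, canonical full-precision format)
# ---------------------------------------------------------------------------

def write_geotiff(path: str | os.PathLike, grid: GridSpec, data: np.ndarray) -> None:
    data = np.asarray(data, dtype=float)
    if data.shape != grid.shape:
        raise AlignmentError(f"data shape {data.shape} != grid {grid.shape}")
    out = np.where(np.isnan(data), grid.nodata, data)
    cs = float(grid.cell_size)
    # Tie the raster's top-left corner (0,0) to map (xmin, ymax).
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.xmin, grid.ymax, 0.0)),
        (_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(path, out, dtype=np.float64, extratags=extratags)


def read_geotiff(path: str | os.PathLike) -> tuple[GridSpec, np.ndarray]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        tags = page.tags
        try:
            scale = tags[_MODEL_PIXEL_SCALE].value
            tie = tags[_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise ConfigError(f"{path}: TIFF lacks geo-referencing tags") from exc
        nodata = -9999.0
        if _GDAL_NODATA in tags:
            nodata = float(tags[_GDAL_NODATA].value)
    data = np.atleast_2d(data)
    nrows, ncols = data.shape
    cs = float(scale[0])
    if abs(float(scale[1]) - cs) > 1e-9 * cs:
        raise ConfigError(f"{path}: non-square cells are not supported")
    xmin = float(tie[3])
    ymax = float(tie[4])
    grid = GridSpec(nrows=nrows, ncols=ncols, cell_size=cs,
                    origin_x=xmin, origin_y=ymax - nrows * cs, nodata=nodata)
    data[data == nodata] = np.nan
    return grid, data


# ---------------------------------------------------------------------------
# Dispatch and stacks
# ---------------------------------------------------------------------------

_ASCII_EXT = {".asc", ".txt"}
_TIFF_EXT = {".tif", ".tiff"}


def read_raster(path: str | os.PathLike) -> tuple[GridSpec, np.ndarray]:
    ext = Path(path).suffix.lower()
    if ext in _ASCII_EXT:
        return read_ascii_grid(path)
    if ext in _TIFF_EXT:
        return read_geotiff(path)
    raise ConfigError(f"unsupported raster extension {ext!r} for {path}")


def write_raster(path: str | os.PathLike, grid: GridSpec, data: np.ndarray) -> None:
    ext = Path(path).suffix.lower()
    if ext in _ASCII_EXT:
        write_ascii_grid(path, grid, data)
    elif ext in _TIFF_EXT:
        write_geotiff(path, grid, data)
    else:
        raise ConfigError(f"unsupported raster extension {ext!r} for {path}")


def read_stack(paths: list[str | os.PathLike],
               names: list[str] | None = None,
               categorical: set[str] | None = None) -> PredictorStack:
    """Read per-layer raster files into one aligned stack.

    Layer names default to file stems. Files on mismatched grids are
    rejected with an :class:`AlignmentError` naming the offending layer.
    """
    if not paths:
        raise ConfigError("read_stack needs at least one path")
    if names is None:
        names = [Path(p).stem for p in paths]
    if len(names) != len(paths):
        raise ConfigError("names and paths differ in length")
    grid = None
    layers: dict[str, np.ndarray] = {}
    for name, path in zip(names, paths):
        g, data = read_raster(path)
        if grid is None:
            grid = g
        elif not g.same_geometry(grid):
            raise AlignmentError(
                f"layer {name!r} ({path}) is on a different grid "
                f"(cell {g.cell_size} vs {grid.cell_size}, shape {g.shape} vs {grid.shape})")
        if name in layers:
            raise ConfigError(f"duplicate layer name {name!r}")
        layers[name] = data
    return PredictorStack(grid, layers, categorical=categorical)


def write_stack(stack: PredictorStack, directory: str | os.PathLike,
                fmt: str = "ascii") -> list[Path]:
    """Write every layer of a stack as ``<directory>/<name>.<ext>``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = {"ascii": ".asc", "gtiff": ".tif"}.get(fmt)
    if ext is None:
        raise ConfigError(f"unknown format {fmt!r}; use 'ascii' or 'gtiff'")
    paths = []
    for name, data in stack.layers.items():
        path = directory / f"{name}{ext}"
        write_raster(path, stack.grid, data)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Point tables
# ---------------------------------------------------------------------------

def read_points(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path)
    if not {"x", "y"} <= set(table.columns):
        raise ConfigError(f"{path}: point CSV must have columns 'x' and 'y'")
    return table


def write_points(points: pd.DataFrame, path: str | os.PathLike) -> None:
    points.to_csv(path, index=False)
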