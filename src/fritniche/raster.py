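"""Georeferenced raster grids and stacks.

All grids live in WGS84 lon/lat. A :class:`RasterGrid` is a 2-D float array
with NaN marking nodata plus an affine north-up geotransform (west edge,
north edge, square-ish cell sizes in degrees). A :class:`RasterStack` is a
set of named, grid-aligned layers (e.g. bioclimatic variables).

I/O: ESRI ASCII Grid (plain text) and GeoTIFF (via tifffile, with
ModelPixelScale / ModelTiepoint / GeoKey tags so GIS tools see WGS84).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

WGS84 = "EPSG:4326"

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_NODATA = 42113


@dataclass
class RasterGrid:
    """A single 2-D layer; NaN cells are nodata."""

    values: np.ndarray
    west: float
    north: float
    dx: float
    dy: float
    crs: str = WGS84
    name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def south(self) -> float:
        return self.north - self.shape[0] * self.dy

    @property
    def east(self) -> float:
        return self.west + self.shape[1] * self.dx

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def lons(self) -> np.ndarray:
        """Cell-centre longitudes (one per column)."""
        return self.west + (np.arange(self.shape[1]) + 0.5) * self.dx

    def lats(self) -> np.ndarray:
        """Cell-centre latitudes (one per row, north to south)."""
        return self.north - (np.arange(self.shape[0]) + 0.5) * self.dy

    def index_of(self, lon, lat):
        """Row/col of the cell containing (lon, lat); None-masked array for
        points outside the extent."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.dx).astype(int)
        row = np.floor((self.north - lat) / self.dy).astype(int)
        inside = (col >= 0) & (col < self.shape[1]) & (row >= 0) & (row < self.shape[0])
        return row, col, inside

    def value_at(self, lon: float, lat: float) -> float:
        row, col, inside = self.index_of(lon, lat)
        if not inside:
            return float("nan")
        return float(self.values[row, col])

    def cell_center(self, row, col):
        lon = self.west + (np.asarray(col) + 0.5) * self.dx
        lat = self.north - (np.asarray(row) + 0.5) * self.dy
        return lon, lat

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.west, other.west)
            and np.isclose(self.north, other.north)
            and np.isclose(self.dx, other.dx)
            and np.isclose(self.dy, other.dy)
        )

    def like(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        """A new grid with the same georeferencing but different values."""
        return replace(self, values=np.asarray(values, dtype=float),
                       name=name if name is not None else self.name)


@dataclass
class RasterStack:
    """Named, aligned environmental layers sharing one geotransform."""

    names: list[str]
    data: np.ndarray  # (n_layers, n_rows, n_cols)
    west: float
    north: float
    dx: float
    dy: float
    crs: str = WGS84

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.names):
            raise ValueError("data must be (n_layers, n_rows, n_cols) matching names")

    @property
    def n_layers(self) -> int:
        return len(self.names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def layer(self, name: str) -> RasterGrid:
        i = self.names.index(name)
        return RasterGrid(self.data[i], self.west, self.north, self.dx, self.dy,
                          crs=self.crs, name=name)

    def grid_template(self) -> RasterGrid:
        return RasterGrid(np.full(self.shape, np.nan), self.west, self.north,
                          self.dx, self.dy, crs=self.crs)

    @property
    def valid(self) -> np.ndarray:
        """Cells valid (non-nodata) in every layer."""
        return np.all(np.isfinite(self.data), axis=0)

    def table(self, mask: np.ndarray | None = None):
        """Flatten layers to an (n_cells, n_layers) table over ``mask``
        (default: jointly valid cells). Returns (array, rows, cols)."""
        if mask is None:
            mask = self.valid
        rows, cols = np.nonzero(mask)
        return self.data[:, rows, cols].T.copy(), rows, cols

    @classmethod
    def from_grids(cls, grids: list[RasterGrid]) -> "RasterStack":
        base = grids[0]
        for g in grids[1:]:
            if not g.aligned_with(base):
                raise ValueError(f"layer {g.name!r} not aligned with {base.name!r}")
        return cls([g.name for g in grids], np.stack([g.values for g in grids]),
                   base.west, base.north, base.dx, base.dy, crs=base.crs)


# ---------------------------------------------------------------------------
# ESRI ASCII Grid

def write_ascii(grid: RasterGrid, path, nodata: float = -9999.0) -> None:
    if not np.isclose(grid.dx, grid.dy):
        raise ValueError("ESRI ASCII requires square cells")
    vals = np.where(grid.valid, grid.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {float(grid.west)!r}\n")
        fh.write(f"yllcorner {float(grid.south)!r}\n")
        fh.write(f"cellsize {float(grid.dx)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii(path, name: str | None = None) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    idx = 0
    for idx, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value", "xllcenter", "yllcenter",
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    required = {"ncols", "nrows", "cellsize"}
    if not required <= set(header) or not (
        {"xllcorner", "xllcenter"} & set(header)
    ):
        raise ValueError(f"corrupt ESRI ASCII header in {path}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    west = header.get("xllcorner", header.get("xllcenter", 0.0) - cell / 2)
    south = header.get("yllcorner", header.get("yllcenter", 0.0) - cell / 2)
    nodata = header.get("nodata_value", -9999.0)
    body = " ".join(lines[idx:])
    vals = np.array(body.split(), dtype=float)
    if vals.size != nrows * ncols:
        raise ValueError(f"corrupt ESRI ASCII body in {path}: "
                         f"expected {nrows * ncols} values, found {vals.size}")
    vals = vals.reshape(nrows, ncols)
    vals[vals == nodata] = np.nan
    return RasterGrid(vals, west=west, north=south + nrows * cell,
                      dx=cell, dy=cell, name=name or "layer")


# ---------------------------------------------------------------------------
# GeoTIFF (tifffile + manual geo tags)

def _wgs84_geokeys() -> tuple[int, ...]:
    # GeoKeyDirectory: version 1.1.0, 3 keys:
    #   GTModelTypeGeoKey=2 (geographic), GTRasterTypeGeoKey=1 (PixelIsArea),
    #   GeographicTypeGeoKey=4326 (WGS84)
    return (1, 1, 0, 3,
            1024, 0, 1, 2,
            1025, 0, 1, 1,
            2048, 0, 1, 4326)


def write_geotiff(grid: RasterGrid, path, nodata: float = -9999.0) -> None:
    import tifffile

    vals = np.where(grid.valid, grid.values, nodata).astype(np.float64)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.dx, grid.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.west, grid.north, 0.0)),
        (_TAG_GEOKEYS, "H", 16, _wgs84_geokeys()),
        (_TAG_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_geotiff(path, name: str | None = None) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        vals = page.asarray().astype(float)
        tags = {t.code: t.value for t in page.tags.values()}
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise ValueError(f"corrupt or non-georeferenced GeoTIFF: {path}")
    dx, dy = tags[_TAG_PIXEL_SCALE][0], tags[_TAG_PIXEL_SCALE][1]
    tie = tags[_TAG_TIEPOINT]
    west = tie[3] - tie[0] * dx
    north = tie[4] + tie[1] * dy
    if _TAG_GEOKEYS not in tags:
        warnings.warn(f"{path}: no CRS tags; assuming WGS84 lon/lat")
        logger.warning("%s: no CRS tags; assuming WGS84", path)
    nodata = float(tags[_TAG_NODATA]) if _TAG_NODATA in tags else None
    if nodata is not None:
        vals[vals == nodata] = np.nan
    return RasterGrid(vals, west=west, north=north, dx=dx, dy=dy,
                      name=name or "layer")


def read_raster(path, name: str | None = None) -> RasterGrid:
    """Dispatch on extension: .asc/.txt -> ESRI ASCII, .tif/.tiff -> GeoTIFF."""
    p = str(path).lower()
    if p.endswith((".tif", ".tiff")):
        return read_geotiff(path, name=name)
    return read_ascii(path, name=name)


def write_raster(grid: RasterGrid, path, nodata: float = -9999.0) -> None:
    p = str(path).lower()
    if p.endswith((".tif", ".tiff")):
        write_geotiff(grid, path, nodata=nodata)
    else:
        write_ascii(grid, path, nodata=nodata)


def cell_area_km2(grid: RasterGrid) -> np.ndarray:
    """Per-cell spherical area in km^2: R^2 * dlon * dlat * cos(lat),
    R = 6371.0088 km, angles in radians; one value per row broadcast over
    columns."""
    R = 6371.0088
    lat = np.deg2rad(grid.lats())
    dlam = np.deg2rad(grid.dx)
    dphi = np.deg2rad(grid.dy)
    per_row = R * R * dlam * dphi * np.cos(lat)
    return np.repeat(per_row[:, None], grid.shape[1], axis=1)
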