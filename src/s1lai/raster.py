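"""Minimal north-up single-band raster container with ESRI ASCII-grid I/O.

The pipeline only needs square-pixel, north-up grids on a projected CRS
(10 m Sentinel-1 post-processing grids), so the container stores the grid
as (x_min, y_max, cell) rather than a full affine transform.  Rasters are
persisted as plain-text ESRI ASCII grids (``.asc``), one band per file;
the CRS tag travels in-memory and in run manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class Raster:
    """A single-band float raster on a north-up square-pixel grid."""

    data: np.ndarray          # 2-D float array, NODATA marks missing
    x_min: float              # west edge of the west-most column
    y_max: float              # north edge of the north-most row
    cell: float               # pixel size in CRS units (m)
    crs: str = "EPSG:32720"
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x_min, other.x_min)
            and np.isclose(self.y_max, other.y_max)
            and np.isclose(self.cell, other.cell)
            and self.crs == other.crs
        )

    # -- coordinate helpers ------------------------------------------------
    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Pixel containing point (x, y); half-open pixel intervals."""
        col = int(np.floor((x - self.x_min) / self.cell))
        row = int(np.floor((self.y_max - y) / self.cell))
        nr, nc = self.shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise ValueError(f"point ({x}, {y}) outside raster bounds")
        return row, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.rowcol(x, y)
        return float(self.data[r, c])

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate grids, each of raster shape."""
        nr, nc = self.shape
        xs = self.x_min + (np.arange(nc) + 0.5) * self.cell
        ys = self.y_max - (np.arange(nr) + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def mask_valid(self) -> np.ndarray:
        return self.data != self.nodata

    def copy_with(self, data: np.ndarray) -> "Raster":
        return Raster(np.asarray(data, dtype=np.float64), self.x_min,
                      self.y_max, self.cell, self.crs, self.nodata)


def write_ascii(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (plain text, GDAL-readable)."""
    nr, nc = raster.shape
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {raster.x_min:.6f}\n"
        f"yllcorner {raster.y_max - nr * raster.cell:.6f}\n"
        f"cellsize {raster.cell:.6f}\n"
        f"NODATA_value {raster.nodata:.1f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.data, fmt="%.6f")


def read_ascii(path: str | Path, crs: str = "EPSG:32720") -> Raster:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nrows = int(meta["nrows"])
    if data.shape != (nrows, int(meta["ncols"])):
        raise ValueError(f"grid shape mismatch in {path}")
    y_max = meta["yllcorner"] + nrows * meta["cellsize"]
    return Raster(data, meta["xllcorner"], y_max, meta["cellsize"], crs,
                  meta.get("nodata_value", NODATA))


def polygon_mask(raster: Raster, polygons) -> np.ndarray:
    """Boolean mask of pixels whose *center* falls inside any polygon."""
    from shapely import contains_xy
    from shapely.ops import unary_union

    polys = list(polygons)
    if not polys:
        return np.zeros(raster.shape, dtype=bool)
    merged = unary_union(polys)
    xg, yg = raster.pixel_centers()
    return contains_xy(merged, xg.ravel(), yg.ravel()).reshape(raster.shape)
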