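"""Grid geometry and raster I/O.

All rasters in a run live on a single rectangular grid of square cells whose
size is expressed in kilometres, so every distance or area computation is
plain Euclidean geometry.  Rasters are 2-D float arrays with NaN marking
nodata; boolean rasters carry an explicit validity mask.  Files are written
as float32 TIFF (one page per band) with the grid geometry and band names
embedded as JSON in the image description tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import tifffile

from .errors import InvalidParameterError

__all__ = ["GridSpec", "write_raster", "read_raster"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the common analysis grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid shape; rows index northing (row 0 is the southern edge).
    cell_size_km : float
        Side length of a square cell in km (5 km mimics a 0.05 degree cell
        at tropical latitudes).
    origin_x, origin_y : float
        Coordinates (km) of the south-west corner of the grid.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 5.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata_value: float | None = None  # None means NaN-coded nodata

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidParameterError("grid must have at least one row and column")
        if not self.cell_size_km > 0:
            raise InvalidParameterError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates in km, each shaped (n_rows, n_cols)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size_km
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size_km
        return np.meshgrid(xs, ys)

    def northing(self) -> np.ndarray:
        """Northing (km from origin_y) of each cell center, shape (n_rows, n_cols)."""
        return self.cell_centers()[1] - self.origin_y

    def point_to_cell(self, x: float, y: float) -> tuple[int, int] | None:
        """Row/col of the cell containing (x, y), or None if off-grid."""
        col = int(np.floor((x - self.origin_x) / self.cell_size_km))
        row = int(np.floor((y - self.origin_y) / self.cell_size_km))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


def write_raster(path, data: np.ndarray, grid: GridSpec, band_names=None) -> None:
    """Write a (bands, rows, cols) or (rows, cols) float raster as TIFF.

    Grid geometry and band names travel in the description tag so a raster
    file round-trips without sidecar files.
    """
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.shape[1:] != grid.shape:
        raise InvalidParameterError(
            f"raster shape {arr.shape[1:]} does not match grid {grid.shape}"
        )
    meta = {"grid": grid.to_dict(), "band_names": list(band_names or [])}
    tifffile.imwrite(
        str(path), arr, photometric="minisblack", description=json.dumps(meta)
    )


def read_raster(path) -> tuple[np.ndarray, GridSpec, list[str]]:
    """Read a TIFF written by :func:`write_raster`.

    Returns (bands, rows, cols) float64 data, the grid, and band names.
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray().astype(np.float64)
        desc = tif.pages[0].description
    if arr.ndim == 2:
        arr = arr[None, :, :]
    meta = json.loads(desc)
    grid = GridSpec.from_dict(meta["grid"])
    return arr, grid, meta.get("band_names", [])
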