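"""Regular latitude-longitude grids and spherical-Earth cell areas.

The analysis grid is a regular geographic (WGS-84) grid with square cells of
``res`` degrees. Row 0 is the northmost row; cell ``(i, j)`` covers latitudes
``[origin_lat - (i+1)*res, origin_lat - i*res)`` (south edge inclusive) and
longitudes ``[origin_lon + j*res, origin_lon + (j+1)*res)`` (west edge
inclusive).

Cell areas use the spherical band formula

    A = R^2 * dlambda * (sin(phi_top) - sin(phi_bottom))

which is exact on the sphere, so the areas of a full global grid close to
4*pi*R^2 to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: Authalic Earth radius in km (sphere of equal surface area to the ellipsoid).
EARTH_RADIUS_KM = 6371.0072


@dataclass(frozen=True)
class GridSpec:
    """A regular lat-lon grid: north-west origin, row 0 northmost."""

    origin_lat: float
    origin_lon: float
    n_rows: int
    n_cols: int
    res: float

    def __post_init__(self) -> None:
        if not self.res > 0:
            raise ValidationError(f"grid resolution must be > 0, got {self.res}")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValidationError("grid must have positive n_rows and n_cols")
        if self.n_rows * self.res > 180 + 1e-9:
            raise ValidationError("grid spans more than 180 degrees of latitude")
        if self.n_cols * self.res > 360 + 1e-9:
            raise ValidationError("grid spans more than 360 degrees of longitude")
        if not (-90 - 1e-9 <= self.origin_lat - self.n_rows * self.res
                and self.origin_lat <= 90 + 1e-9):
            raise ValidationError("grid latitude extent outside [-90, 90]")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat_edges(self) -> np.ndarray:
        """Latitudes of the n_rows + 1 row edges, north to south."""
        return self.origin_lat - self.res * np.arange(self.n_rows + 1)

    def lon_edges(self) -> np.ndarray:
        return self.origin_lon + self.res * np.arange(self.n_cols + 1)

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) of cell centres; accepts scalars or arrays."""
        row = np.asarray(row)
        col = np.asarray(col)
        lat = self.origin_lat - (row + 0.5) * self.res
        lon = self.origin_lon + (col + 0.5) * self.res
        return lat, lon


def make_grid(origin_lat: float, origin_lon: float, n_rows: int, n_cols: int,
              res: float) -> GridSpec:
    """Validate and build a :class:`GridSpec`."""
    return GridSpec(float(origin_lat), float(origin_lon), int(n_rows),
                    int(n_cols), float(res))


def global_grid(res: float) -> GridSpec:
    """A full global grid at the given resolution (res must divide 180)."""
    n_rows = round(180 / res)
    n_cols = round(360 / res)
    return make_grid(90.0, -180.0, n_rows, n_cols, res)


def cell_of(lat, lon, grid: GridSpec):
    """Map points to (row, col) cells under the half-open cell convention.

    Accepts scalars or equal-length arrays. Returns integer arrays
    ``(rows, cols, in_domain)`` where ``in_domain`` is False for points outside
    the grid; out-of-domain rows/cols are set to -1. Scalars in, scalars out.

    The south and west cell edges are inclusive: a point exactly on the shared
    edge of two cells belongs to the southern/western interval's owner cell,
    i.e. row = ceil((origin_lat - lat)/res) - 1, col = floor((lon - origin_lon)/res).
    """
    scalar = np.isscalar(lat) and np.isscalar(lon)
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    if lat.shape != lon.shape:
        raise ValidationError("lat and lon must have the same shape")
    if np.isnan(lat).any() or np.isnan(lon).any():
        raise ValidationError("NaN coordinates are not valid")

    rows = np.ceil((grid.origin_lat - lat) / grid.res).astype(np.int64) - 1
    cols = np.floor((lon - grid.origin_lon) / grid.res).astype(np.int64)
    in_domain = ((rows >= 0) & (rows < grid.n_rows)
                 & (cols >= 0) & (cols < grid.n_cols))
    rows = np.where(in_domain, rows, -1)
    cols = np.where(in_domain, cols, -1)
    if scalar:
        return int(rows[0]), int(cols[0]), bool(in_domain[0])
    return rows, cols, in_domain


def cell_area(grid: GridSpec, row: int, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Area in km^2 of any cell in ``row`` (all cells of a row are equal)."""
    if not 0 <= row < grid.n_rows:
        raise IndexError(f"row {row} out of range for {grid.n_rows}-row grid")
    return float(row_areas(grid, radius_km)[row])


def row_areas(grid: GridSpec, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Per-row cell areas (km^2), spherical band formula."""
    edges = np.deg2rad(grid.lat_edges())
    dlam = np.deg2rad(grid.res)
    sin_e = np.sin(edges)
    return radius_km ** 2 * dlam * (sin_e[:-1] - sin_e[1:])


def area_raster(grid: GridSpec, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Full (n_rows, n_cols) array of cell areas in km^2."""
    return np.broadcast_to(row_areas(grid, radius_km)[:, None], grid.shape).copy()
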