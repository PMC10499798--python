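"""Raster containers, GeoTIFF input/output, and occurrence-point reading.

Rasters are plain numpy arrays tied to a :class:`~suitmap.grid.GridSpec` with
an explicit nodata mask. On disk they are single-band GeoTIFFs in WGS-84
geographic coordinates with square cells and an explicit nodata value; the
georeferencing is carried by the standard GeoTIFF tags (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory) plus GDAL's ASCII nodata tag, so the files
interoperate with GDAL-based stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, GridMismatchError, ValidationError
from .grid import GridSpec, make_grid

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_MODEL_TRANSFORMATION = 34264
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKeyDirectory: version 1.1.0, 3 keys:
#   GTModelType = 2 (geographic), GTRasterType = 1 (PixelIsArea),
#   GeographicType = 4326 (WGS-84)
_GEO_KEYS = (1, 1, 0, 3,
             1024, 0, 1, 2,
             1025, 0, 1, 1,
             2048, 0, 1, 4326)


@dataclass
class Raster:
    """A single-band raster on a regular lat-lon grid.

    ``mask`` is True where a cell is nodata (numpy.ma convention).
    """

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"raster shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask shape must match values shape")

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return ~self.mask

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.mask.copy())

    @classmethod
    def full(cls, grid: GridSpec, fill: float = 0.0,
             dtype=np.float64) -> "Raster":
        return cls(grid, np.full(grid.shape, fill, dtype=dtype),
                   np.zeros(grid.shape, dtype=bool))


@dataclass
class CovariateStack:
    """Named co-registered covariate layers sharing one grid.

    ``climate_layers`` names the layers that scenario shifts may touch;
    topography and soil layers stay fixed across scenarios.
    """

    grid: GridSpec
    layers: dict[str, Raster] = field(default_factory=dict)
    climate_layers: tuple[str, ...] = ()
    categorical_layers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, layer in self.layers.items():
            if layer.grid != self.grid:
                raise GridMismatchError(f"layer {name!r} is not on the stack grid")
        unknown = set(self.climate_layers) - set(self.layers)
        if unknown:
            raise ValidationError(f"climate_layers not in stack: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def joint_valid(self) -> np.ndarray:
        """Intersection of per-layer validity masks."""
        valid = np.ones(self.grid.shape, dtype=bool)
        for layer in self.layers.values():
            valid &= layer.valid
        return valid

    def select(self, names) -> "CovariateStack":
        names = list(names)
        missing = set(names) - set(self.layers)
        if missing:
            raise ValidationError(f"unknown layers: {sorted(missing)}")
        return CovariateStack(
            self.grid, {n: self.layers[n] for n in names},
            tuple(n for n in self.climate_layers if n in names),
            tuple(n for n in self.categorical_layers if n in names))

    def with_layer(self, name: str, raster: Raster) -> "CovariateStack":
        layers = dict(self.layers)
        layers[name] = raster
        return replace(self, layers=layers)


@dataclass
class LandCoverMap:
    """Integer land-cover class codes plus a code -> name legend."""

    raster: Raster
    legend: dict[int, str]

    def __post_init__(self) -> None:
        codes = np.unique(self.raster.values[self.raster.valid])
        missing = [int(c) for c in codes if int(c) not in self.legend]
        if missing:
            raise ValidationError(f"land-cover codes missing from legend: {missing}")


@dataclass
class RegionMap:
    """Integer region IDs partitioning the valid domain, with a name table."""

    raster: Raster
    table: pd.DataFrame  # columns: region_id, name, level

    def __post_init__(self) -> None:
        ids = np.unique(self.raster.values[self.raster.valid])
        known = set(int(i) for i in self.table["region_id"])
        missing = [int(i) for i in ids if int(i) not in known]
        if missing:
            raise ValidationError(f"region IDs missing from table: {missing}")

    def name_of(self, region_id: int) -> str:
        row = self.table.loc[self.table["region_id"] == region_id, "name"]
        return str(row.iloc[0])


@dataclass
class SuitabilityMap:
    """Per-cell environmental suitability in [0, 1], optional SD companion."""

    mean: Raster
    sd: Raster | None = None

    def __post_init__(self) -> None:
        vals = self.mean.values[self.mean.valid]
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
            raise ValidationError("suitability values must lie in [0, 1]")
        if self.sd is not None and self.sd.grid != self.mean.grid:
            raise GridMismatchError("SD layer is not on the suitability grid")

    @property
    def grid(self) -> GridSpec:
        return self.mean.grid

    @property
    def valid(self) -> np.ndarray:
        return self.mean.valid


def _default_nodata(dtype: np.dtype) -> float:
    if np.issubdtype(dtype, np.integer):
        return int(np.iinfo(dtype).min)
    return -9999.0


def write_raster(raster: Raster, path, nodata=None) -> None:
    """Write a single-band georeferenced GeoTIFF with explicit nodata."""
    values = np.asarray(raster.values)
    if nodata is None:
        nodata = _default_nodata(values.dtype)
    out = values.copy()
    out[raster.mask] = nodata
    grid = raster.grid
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, 'd', 3, (grid.res, grid.res, 0.0)),
        (_TAG_MODEL_TIEPOINT, 'd', 6,
         (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, 'H', len(_GEO_KEYS), _GEO_KEYS),
        (_TAG_GDAL_NODATA, 's', 0, str(nodata)),
    ]
    tifffile.imwrite(path, out, photometric='minisblack', extratags=extratags)


def read_raster(path) -> Raster:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or GDAL).

    Requires axis-aligned square cells; a rotated ModelTransformation or
    missing georeferencing raises :class:`FormatError`.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = {tag.code: tag.value for tag in page.tags.values()}
        data = page.asarray()
    if data.ndim != 2:
        raise FormatError("expected a single-band raster")
    if _TAG_MODEL_TRANSFORMATION in tags:
        raise FormatError("rotated/general model transformations are not supported")
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise FormatError("raster lacks GeoTIFF georeferencing tags")
    sx, sy = tags[_TAG_MODEL_PIXEL_SCALE][:2]
    if abs(sx - sy) > 1e-9 * max(abs(sx), abs(sy)):
        raise FormatError(f"cells are not square: scale = ({sx}, {sy})")
    tie = tags[_TAG_MODEL_TIEPOINT]
    if tuple(tie[:2]) != (0.0, 0.0):
        raise FormatError("tiepoint must anchor the (0, 0) pixel corner")
    origin_lon, origin_lat = tie[3], tie[4]
    grid = make_grid(origin_lat, origin_lon, data.shape[0], data.shape[1], sx)
    nodata_tag = tags.get(_TAG_GDAL_NODATA)
    if nodata_tag is None:
        mask = np.zeros(data.shape, dtype=bool)
    else:
        nodata = float(nodata_tag)
        if np.issubdtype(data.dtype, np.integer):
            mask = data == int(nodata)
        elif np.isnan(nodata):
            mask = np.isnan(data)
        else:
            mask = data == nodata
    return Raster(grid, data, mask)


def read_points(path, lat_col: str = "lat", lon_col: str = "lon"):
    """Read occurrence points from CSV; returns (points, n_dropped).

    ``points`` is an (n, 2) float array of (lat, lon). Rows with missing or
    out-of-range coordinates (|lat| > 90, |lon| > 180) are dropped and counted.
    Column names are matched case-insensitively, accepting the common
    ``latitude``/``longitude`` spellings as well. Extra columns are ignored.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    lat_name = cols.get(lat_col.lower()) or cols.get("latitude")
    lon_name = cols.get(lon_col.lower()) or cols.get("longitude")
    if lat_name is None or lon_name is None:
        raise FormatError(
            f"point file must have latitude/longitude columns; found {list(df.columns)}")
    lat = pd.to_numeric(df[lat_name], errors="coerce")
    lon = pd.to_numeric(df[lon_name], errors="coerce")
    ok = lat.notna() & lon.notna() & (lat.abs() <= 90) & (lon.abs() <= 180)
    pts = np.column_stack([lat[ok].to_numpy(float), lon[ok].to_numpy(float)])
    return pts, int((~ok).sum())


def write_points(points: np.ndarray, path) -> None:
    pd.DataFrame(points, columns=["lat", "lon"]).to_csv(path, index=False)
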