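"""Slope derivation from elevation on a geographic grid.

Slope is the Horn (1981) 3x3 finite-difference gradient magnitude, the same
stencil GIS packages use, converted to degrees. Horizontal distances are
latitude-corrected: one degree of longitude shrinks by cos(latitude), with the
metres-per-degree constant taken from the package's spherical Earth model.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .grid import EARTH_RADIUS_KM
from .raster import Raster

#: metres per degree of latitude on the model sphere
M_PER_DEG = np.pi * EARTH_RADIUS_KM * 1000.0 / 180.0


def slope_from_elevation(elev: Raster) -> Raster:
    """Slope in degrees from an elevation raster in metres.

    Cells without a fully valid 3x3 neighbourhood (including the outer edge of
    the grid) become nodata.
    """
    if not elev.valid.any():
        raise ValidationError("elevation raster has no valid cells")
    z = np.asarray(elev.values, dtype=float)
    n_rows, n_cols = z.shape

    def sh(di: int, dj: int) -> np.ndarray:
        """Neighbour value at offset (di, dj); edges padded with NaN."""
        out = np.full_like(z, np.nan)
        src = z.copy()
        src[elev.mask] = np.nan
        out[max(0, -di):n_rows - max(0, di),
            max(0, -dj):n_cols - max(0, dj)] = \
            src[max(0, di):n_rows - max(0, -di),
                max(0, dj):n_cols - max(0, -dj)]
        return out

    a, b, c = sh(-1, -1), sh(-1, 0), sh(-1, 1)
    d, f = sh(0, -1), sh(0, 1)
    g, h, i = sh(1, -1), sh(1, 0), sh(1, 1)

    lat_c = elev.grid.origin_lat - (np.arange(n_rows) + 0.5) * elev.grid.res
    dx = elev.grid.res * M_PER_DEG * np.cos(np.deg2rad(lat_c))[:, None]
    dy = elev.grid.res * M_PER_DEG

    with np.errstate(invalid="ignore"):
        dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dx)
        dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * dy)
        slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))

    mask = ~np.isfinite(slope) | elev.mask
    slope = np.where(mask, 0.0, slope)
    return Raster(elev.grid, slope, mask)
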