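"""Regular lon/lat grid geometry.

All grids are cell-centered, row-major with row 0 at the northernmost
latitude band. Longitude is periodic; latitude is not (no neighbours
beyond the poles). Distances are great-circle km on a sphere of radius
6371 km; cell areas use the cos(lat) approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0


class ConfigurationError(ValueError):
    """Raised for invalid grid or world configuration."""


@dataclass(frozen=True)
class GridSpec:
    """A global regular grid in degrees.

    Parameters
    ----------
    lon_res, lat_res : float
        Cell size in degrees. Must divide 360 and 180 respectively.
    """

    lon_res: float
    lat_res: float
    lon: np.ndarray = field(init=False, repr=False, compare=False)
    lat: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.lon_res <= 0 or self.lat_res <= 0:
            raise ConfigurationError("grid resolution must be positive")
        nlon = int(round(360 / self.lon_res))
        nlat = int(round(180 / self.lat_res))
        if abs(nlon * self.lon_res - 360) > 1e-6 or abs(nlat * self.lat_res - 180) > 1e-6:
            raise ConfigurationError(
                "lon_res must divide 360 and lat_res must divide 180"
            )
        if nlon < 4 or nlat < 4:
            raise ConfigurationError("degenerate grid: need at least 4x4 cells")
        lon = -180 + self.lon_res * (np.arange(nlon) + 0.5)
        lat = 90 - self.lat_res * (np.arange(nlat) + 0.5)  # north to south
        object.__setattr__(self, "lon", lon)
        object.__setattr__(self, "lat", lat)

    @property
    def nlon(self) -> int:
        return self.lon.size

    @property
    def nlat(self) -> int:
        return self.lat.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    def cell_areas_m2(self) -> np.ndarray:
        """Per-cell area (m^2), proportional to cos(lat), shape (nlat, nlon)."""
        r_m = EARTH_RADIUS_KM * 1e3
        dlam = np.deg2rad(self.lon_res)
        dphi = np.deg2rad(self.lat_res)
        band = r_m**2 * dlam * dphi * np.cos(np.deg2rad(self.lat))
        return np.repeat(band[:, None], self.nlon, axis=1)

    def lat_grid(self) -> np.ndarray:
        return np.repeat(self.lat[:, None], self.nlon, axis=1)

    def lon_grid(self) -> np.ndarray:
        return np.repeat(self.lon[None, :], self.nlat, axis=0)


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine great-circle distance in km (array-broadcasting)."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlam = np.deg2rad(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


# 8-neighbourhood offsets (drow, dcol), row 0 = north.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


def shift(grid: np.ndarray, drow: int, dcol: int, fill=np.nan) -> np.ndarray:
    """Shift a 2-D grid so result[i, j] = grid[i + drow, j + dcol].

    Longitude (columns) wraps; latitude (rows) is clamped with `fill`
    beyond the poles.
    """
    out = np.roll(grid, -dcol, axis=1)
    if drow == 0:
        return out.copy()
    res = np.full(out.shape, fill, dtype=out.dtype)
    if drow > 0:
        res[:-drow, :] = out[drow:, :]
    else:
        res[-drow:, :] = out[:drow, :]
    return res
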