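"""Grid helpers shared across the pipeline.

The analysis grid is a rectangular lat-lon grid of cell centers with
latitude ascending. Area weighting is proportional to cos(latitude),
the standard flat approximation for regular lat-lon grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr


@dataclass(frozen=True)
class GridSpec:
    """Regular lat-lon grid of cell centers.

    Parameters
    ----------
    lat : array of cell-center latitudes, ascending, degrees north
    lon : array of cell-center longitudes, degrees east in [-180, 180)
    """

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self):
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        if lat.ndim != 1 or lon.ndim != 1:
            raise ValueError("lat and lon must be 1-D")
        if np.any(np.diff(lat) <= 0):
            raise ValueError("latitudes must be strictly ascending")
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)

    @classmethod
    def regular(cls, n_lat: int = 20, n_lon: int = 30,
                lat_bounds: tuple[float, float] = (25.0, 50.0),
                lon_bounds: tuple[float, float] = (-125.0, -65.0)) -> "GridSpec":
        """Small rectangular grid standing in for a 0.5-degree continental
        domain; no geographic realism claimed."""
        lat = np.linspace(*lat_bounds, n_lat)
        lon = np.linspace(*lon_bounds, n_lon)
        return cls(lat=lat, lon=lon)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    @property
    def n_cells(self) -> int:
        return self.lat.size * self.lon.size

    def cell_areas(self) -> xr.DataArray:
        """Relative cell areas, proportional to cos(latitude)."""
        w = np.cos(np.deg2rad(self.lat))
        area = np.broadcast_to(w[:, None], self.shape)
        return xr.DataArray(area.copy(), dims=("lat", "lon"),
                            coords={"lat": self.lat, "lon": self.lon},
                            name="cell_area")


def coslat_weights(lat: xr.DataArray | np.ndarray) -> xr.DataArray:
    """cos(latitude) weights, clipped at zero for pole rows."""
    if isinstance(lat, xr.DataArray):
        return np.cos(np.deg2rad(lat)).clip(min=0.0)
    return xr.DataArray(np.clip(np.cos(np.deg2rad(np.asarray(lat))), 0.0, None),
                        dims=("lat",), coords={"lat": np.asarray(lat)})


def normalize_longitudes(obj: xr.DataArray | xr.Dataset, lon_name: str = "lon"):
    """Map a longitude coordinate to [-180, 180) and sort ascending.

    Box selections and index recipes are then encoding-independent: a
    0-360 file and its -180..180 twin give identical results.
    """
    lon = ((obj[lon_name] + 180.0) % 360.0) - 180.0
    out = obj.assign_coords({lon_name: lon})
    return out.sortby(lon_name)
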