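import numpy as np
import pytest
import xarray as xr

from modefire.grids import GridSpec
from modefire.scenario import build_demo_world


def make_monthly_field(values, lat, lon, start_year=2000, name="field"):
    """Build a (member, time, lat, lon) monthly field from raw values.

    ``values`` has shape (n_members, n_months, n_lat, n_lon); the time
    axis is consecutive calendar months from January of ``start_year``.
    """
    values = np.asarray(values, float)
    n_members, n_months = values.shape[:2]
    t0 = np.datetime64(f"{start_year:04d}-01", "M")
    time = (t0 + np.arange(n_months)).astype("datetime64[ns]")
    return xr.DataArray(
        values, dims=("member", "time", "lat", "lon"),
        coords={"member": np.arange(n_members), "time": time,
                "lat": np.asarray(lat, float), "lon": np.asarray(lon, float)},
        name=name,
    )


def make_count_cube(values, lat=None, lon=None):
    """(member, year, month, lat, lon) count cube from raw values."""
    values = np.asarray(values, float)
    n_members, n_years, n_months, n_lat, n_lon = values.shape
    lat = np.arange(n_lat, dtype=float) if lat is None else lat
    lon = np.arange(n_lon, dtype=float) if lon is None else lon
    return xr.DataArray(
        values, dims=("member", "year", "month", "lat", "lon"),
        coords={"member": np.arange(n_members), "year": np.arange(n_years),
                "month": np.arange(1, 13), "lat": lat, "lon": lon},
        name="fire_counts",
    )


def annual_series(values):
    """(member, year) index series from raw values."""
    values = np.asarray(values, float)
    return xr.DataArray(values, dims=("member", "year"),
                        coords={"member": np.arange(values.shape[0]),
                                "year": np.arange(values.shape[1])})


@pytest.fixture(scope="session")
def demo_world():
    return build_demo_world(n_members=15, n_years=10, seed=1)


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec.regular(4, 5)
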