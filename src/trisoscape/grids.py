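"""Regular lon/lat raster container for monthly climate and isotope fields.

``ClimateGrid`` wraps an :class:`xarray.Dataset` with a pinned convention:
cell-center coordinates, ascending regular ``lat``/``lon`` axes, an optional
``month`` dimension (1..12) for monthly fields, and a ``units`` attribute on
every data variable. Longitudes live in [-180, 180).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .cellulose import MAY_SEP
from .errors import DataError, DomainError

__all__ = ["ClimateGrid"]


def _check_regular(coord: np.ndarray, name: str) -> None:
    if coord.ndim != 1 or coord.size < 2:
        raise DomainError(f"{name} must be 1-D with at least 2 cells")
    steps = np.diff(coord)
    if np.any(steps <= 0):
        raise DataError(f"{name} must be strictly ascending")
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
        raise DataError(f"{name} spacing is irregular")


@dataclass
class ClimateGrid:
    """A validated regular lon/lat raster of named fields.

    Construct with :meth:`from_dataset` (normalizes descending latitude) or
    :meth:`from_arrays`. Monthly variables carry a leading ``month`` dim.
    """

    ds: xr.Dataset

    def __post_init__(self) -> None:
        for c in ("lat", "lon"):
            if c not in self.ds.coords:
                raise DataError(f"grid is missing coordinate variable '{c}'")
        _check_regular(self.ds["lat"].values, "lat")
        _check_regular(self.ds["lon"].values, "lon")
        if np.any(np.abs(self.ds["lat"].values) > 90):
            raise DataError("latitude outside [-90, 90]")
        lon = self.ds["lon"].values
        if np.any((lon < -180) | (lon >= 360)):
            raise DataError("longitude outside [-180, 360)")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ClimateGrid":
        if "lat" in ds.coords and ds["lat"].size >= 2:
            lat = ds["lat"].values
            if lat[0] > lat[-1]:  # normalize descending-latitude files
                ds = ds.isel(lat=slice(None, None, -1))
        return cls(ds)

    @classmethod
    def from_arrays(cls, lat, lon, **variables) -> "ClimateGrid":
        """Build from coordinate vectors and ``name=(array, units)`` pairs."""
        data = {}
        for name, (arr, units) in variables.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 3:
                dims = ("month", "lat", "lon")
                coords = {"month": np.arange(1, 13)}
                if arr.shape[0] != 12:
                    raise DomainError(f"monthly field '{name}' must have 12 months")
            elif arr.ndim == 2:
                dims, coords = ("lat", "lon"), {}
            else:
                raise DomainError(f"field '{name}' must be 2-D or 3-D")
            data[name] = xr.DataArray(arr, dims=dims, coords=coords, attrs={"units": units})
        ds = xr.Dataset(data, coords={"lat": np.asarray(lat, float), "lon": np.asarray(lon, float)})
        return cls(ds)

    # -- accessors ---------------------------------------------------------

    @property
    def lat(self) -> np.ndarray:
        return self.ds["lat"].values

    @property
    def lon(self) -> np.ndarray:
        return self.ds["lon"].values

    @property
    def step(self) -> float:
        return float(self.ds["lat"].values[1] - self.ds["lat"].values[0])

    def var(self, name: str) -> xr.DataArray:
        if name not in self.ds.data_vars:
            raise DataError(
                f"variable '{name}' not in grid; available: {sorted(self.ds.data_vars)}"
            )
        return self.ds[name]

    def seasonal_mean(self, name: str, window=MAY_SEP) -> xr.DataArray:
        """Unweighted mean of a monthly field over an inclusive month window."""
        da = self.var(name)
        if "month" not in da.dims:
            raise DomainError(f"'{name}' has no month dimension")
        lo, hi = int(window[0]), int(window[1])
        if not (1 <= lo <= hi <= 12):
            raise DomainError(f"invalid month window {window}")
        out = da.sel(month=slice(lo, hi)).mean("month")
        out.attrs["units"] = da.attrs.get("units", "")
        return out

    def with_var(self, name: str, da: xr.DataArray) -> "ClimateGrid":
        ds = self.ds.copy()
        ds[name] = da
        return ClimateGrid(ds)
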