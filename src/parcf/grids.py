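"""Georeferenced raster containers and plain-text raster I/O.

Grids are regular geographic (EPSG:4326-convention) lat/lon rasters with
cell-center coordinate axes.  Missing data is NaN.  Rasters are written as
ESRI ASCII grids (a plain-text format readable by every GIS) with a JSON
sidecar carrying the units/provenance/period metadata that GeoTIFF tags
would normally hold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, GridMismatchError, UnitsError

LAT_MIN, LAT_MAX = -60.0, 70.0  # coverage of the correction-factor product

VALID_UNITS = ("energy", "quantum")
VALID_PROVENANCE = ("real_sky_land", "real_sky_ocean", "clear_sky", "merged")
SEASONS = ("DJF", "MAM", "JJA", "SON")

#: calendar-month membership of the meteorological seasons
SEASON_MONTHS = {
    "DJF": (12, 1, 2),
    "MAM": (3, 4, 5),
    "JJA": (6, 7, 8),
    "SON": (9, 10, 11),
}


def season_of_month(month: int) -> str:
    for season, months in SEASON_MONTHS.items():
        if month in months:
            return season
    raise ValueError(f"invalid month {month}")


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid with an optional land/ocean designation.

    ``land_mask`` is True over land.  The default synthetic mask consists of
    simple longitude-band "continents", enough to exercise the land/ocean
    merge logic without coastline data.
    """

    lat: np.ndarray
    lon: np.ndarray
    land_mask: np.ndarray | None = None

    def __post_init__(self):
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        d = np.diff(lat)
        if lat.ndim != 1 or lat.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
            raise ConfigurationError("lat axis must be strictly monotone")
        if lat.min() < LAT_MIN - 1e-9 or lat.max() > LAT_MAX + 1e-9:
            raise ConfigurationError(
                f"lat axis must lie within [{LAT_MIN}, {LAT_MAX}] degrees"
            )
        if lon.ndim != 1 or lon.size < 1:
            raise ConfigurationError("lon axis must be a 1-D array")
        if self.land_mask is not None:
            mask = np.asarray(self.land_mask, dtype=bool)
            if mask.shape != self.shape:
                raise ConfigurationError("land_mask shape must match (nlat, nlon)")
            object.__setattr__(self, "land_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    @property
    def lat2d(self) -> np.ndarray:
        return np.broadcast_to(self.lat[:, None], self.shape)

    @property
    def lon2d(self) -> np.ndarray:
        return np.broadcast_to(self.lon[None, :], self.shape)

    @classmethod
    def regular(cls, lat_min=LAT_MIN, lat_max=LAT_MAX, nlat=66, lon_min=-180.0,
                lon_max=180.0, nlon=181, with_land_mask=True) -> "GridSpec":
        """Build an evenly spaced grid of cell centers, optionally with the
        default longitude-band land mask (land where (lon+180) mod 90 < 40)."""
        lat = np.linspace(lat_min, lat_max, nlat)
        lon = np.linspace(lon_min, lon_max, nlon, endpoint=False)
        mask = None
        if with_land_mask:
            mask = np.broadcast_to(
                ((lon + 180.0) % 90.0 < 40.0)[None, :], (nlat, lon.size)
            ).copy()
        return cls(lat=lat, lon=lon, land_mask=mask)

    def nearest_cell(self, lat: float, lon: float) -> tuple[int, int]:
        """Indices of the cell whose center is nearest a point (station matching)."""
        if not (min(self.lat.min(), LAT_MIN) <= lat <= max(self.lat.max(), LAT_MAX)):
            raise ConfigurationError(f"latitude {lat} outside grid coverage")
        return int(np.argmin(np.abs(self.lat - lat))), int(np.argmin(np.abs(self.lon - lon)))

    def same_grid(self, other: "GridSpec", atol=1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat, atol=atol)
            and np.allclose(self.lon, other.lon, atol=atol)
        )


@dataclass
class PARGrid:
    """A single raster of PAR values with units, period and provenance tags.

    ``time`` is a pandas Timestamp locating the grid in the calendar;
    ``freq`` says what the grid represents: a 3-hourly slot ("3h"), a daily
    mean ("D"), a calendar-month mean ("M"), a season composite ("seasonal")
    or an annual mean ("Y").  For seasonal grids ``season`` carries the
    DJF/MAM/JJA/SON label.
    """

    values: np.ndarray
    grid: GridSpec
    units: str
    time: pd.Timestamp
    freq: str = "3h"
    provenance: str = "clear_sky"
    season: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.units not in VALID_UNITS:
            raise UnitsError(f"unknown units {self.units!r}")
        if self.provenance not in VALID_PROVENANCE:
            raise ConfigurationError(f"unknown provenance {self.provenance!r}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ConfigurationError("PAR values must be >= 0 or NaN")
        self.time = pd.Timestamp(self.time)

    def copy_with(self, **kwargs) -> "PARGrid":
        fields = dict(
            values=self.values.copy(), grid=self.grid, units=self.units,
            time=self.time, freq=self.freq, provenance=self.provenance,
            season=self.season,
        )
        fields.update(kwargs)
        return PARGrid(**fields)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class CFGrid:
    """A raster of dimensionless correction factors with a validity mask.

    ``mask`` is True where the CF is defined (clear-sky PAR above the floor
    and real-sky PAR present).  Values above 1 are physical (broken-cloud
    enhancement) and are retained, never clipped.
    """

    values: np.ndarray
    mask: np.ndarray
    grid: GridSpec
    freq: str = "M"
    time: pd.Timestamp | None = None
    season: str | None = None
    years_included: tuple = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise GridMismatchError("CF values/mask shape must match the grid")
        valid = self.values[self.mask]
        if valid.size and np.nanmin(valid) < 0:
            raise ConfigurationError("valid CFs must be >= 0")

    def valid_values(self) -> np.ndarray:
        """1-D array of the CFs at valid cells."""
        return self.values[self.mask]

    def fraction_above_one(self) -> float:
        v = self.valid_values()
        return float(np.mean(v > 1.0)) if v.size else 0.0


# ---------------------------------------------------------------------------
# plain-text raster I/O (ESRI ASCII grid + JSON metadata sidecar)

_NODATA = -9999.0


def _check_uniform(axis, name):
    steps = np.diff(axis)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ConfigurationError(f"{name} axis must be uniform for ASCII-grid export")
    return abs(float(steps[0]))


def write_ascii_grid(path, grid: PARGrid | CFGrid) -> None:
    """Write one raster as an ESRI ASCII grid with a ``.json`` metadata sidecar."""
    path = Path(path)
    gs = grid.grid
    dy = _check_uniform(gs.lat, "lat")
    dx = _check_uniform(gs.lon, "lon")
    if not np.isclose(dx, dy, rtol=1e-6):
        raise ConfigurationError("ASCII grid requires square cells")
    values = grid.values.copy()
    if isinstance(grid, CFGrid):
        values[~grid.mask] = np.nan
    # ESRI ASCII rows run north -> south
    rows = values if gs.lat[0] > gs.lat[-1] else values[::-1]
    out = np.where(np.isfinite(rows), rows, _NODATA)
    header = (
        f"ncols {gs.lon.size}\nnrows {gs.lat.size}\n"
        f"xllcorner {gs.lon.min() - dx / 2:.6f}\nyllcorner {gs.lat.min() - dy / 2:.6f}\n"
        f"cellsize {dx:.6f}\nNODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")
    meta = {
        "type": type(grid).__name__,
        "freq": grid.freq,
        "time": str(grid.time) if grid.time is not None else None,
        "season": grid.season,
    }
    if isinstance(grid, PARGrid):
        meta.update(units=grid.units, provenance=grid.provenance)
    else:
        meta.update(years_included=list(grid.years_included))
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_ascii_grid(path) -> PARGrid | CFGrid:
    """Read a raster written by :func:`write_ascii_grid`."""
    path = Path(path)
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = data.reshape(nrows, ncols)
    data[data == header["nodata_value"]] = np.nan
    cell = header["cellsize"]
    lon = header["xllcorner"] + cell / 2 + cell * np.arange(ncols)
    lat_top_down = header["yllcorner"] + cell / 2 + cell * np.arange(nrows)[::-1]
    # store south -> north
    lat = lat_top_down[::-1]
    values = data[::-1]
    gs = GridSpec(lat=lat, lon=lon)
    meta = json.loads(Path(str(path) + ".json").read_text())
    if meta["type"] == "PARGrid":
        return PARGrid(
            values=values, grid=gs, units=meta["units"],
            time=pd.Timestamp(meta["time"]), freq=meta["freq"],
            provenance=meta["provenance"], season=meta["season"],
        )
    return CFGrid(
        values=values, mask=np.isfinite(values), grid=gs, freq=meta["freq"],
        time=pd.Timestamp(meta["time"]) if meta["time"] else None,
        season=meta["season"], years_included=tuple(meta.get("years_included", ())),
    )


def cf_to_csv(cf: CFGrid, path) -> None:
    """Export a CF raster as tidy CSV (lat, lon, cf), valid cells only."""
    gs = cf.grid
    ii, jj = np.where(cf.mask)
    pd.DataFrame(
        {"lat": gs.lat[ii], "lon": gs.lon[jj], "cf": cf.values[ii, jj]}
    ).to_csv(path, index=False)
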