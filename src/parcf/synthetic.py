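"""Synthetic real-sky PAR emulator.

Generates gridded "satellite" PAR and station series with the statistical
structure the correction-factor analysis assumes, so the full pipeline is
testable without any downloads.  Real-sky PAR is modeled as

    real-sky = clear-sky x T(lat, day) x noise,

where the deterministic transmittance profile T carries the three
qualitative features of global cloud climatology that shape the CFs: a
depressed band near the equator (the inter-tropical convergence zone), a
transmittance maximum in the southern subtropics near 20 deg S, and a
strong winter depression poleward of ~40 degrees; and the noise is a
spatially correlated multiplicative lognormal field with median 1
(exponential correlogram), one independent field per day.

The land-style product is 3-hourly in energy units (W m^-2) over land cells
only; the ocean-style product is daily in quantum units
(mol photon m^-2 day^-1) over ocean cells only — mirroring the disjoint
coverage of the satellite products they emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, UnitsError
from .grids import LAT_MAX, LAT_MIN, GridSpec, PARGrid, write_ascii_grid
from .units import energy_to_quantum

_NH_WINTER_SOLSTICE_DOY = 355
_SH_WINTER_SOLSTICE_DOY = 172
_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class CloudModelParams:
    """Parameters of the synthetic cloud-transmittance field.

    All depth parameters must stay below ``base_transmittance`` so the
    deterministic profile remains positive everywhere.
    """

    base_transmittance: float = 0.90
    itcz_center_lat: float = 5.0  # degrees; mean ITCZ position is north of the equator
    itcz_depth: float = 0.25
    itcz_width: float = 10.0  # degrees (Gaussian sigma)
    high_lat_winter_depth: float = 0.45
    high_lat_onset: float = 40.0  # degrees
    storm_track_depth: float = 0.12  # non-seasonal mid-latitude cloud bands
    storm_track_center: float = 50.0  # degrees (both hemispheres)
    storm_track_width: float = 12.0  # degrees (Gaussian sigma)
    noise_sd: float = 0.10
    correlation_length: float = 5.0  # degrees
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.base_transmittance <= 1:
            raise ConfigurationError("base_transmittance must be in (0, 1]")
        for name in ("itcz_depth", "high_lat_winter_depth", "storm_track_depth"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigurationError(f"{name} must be in [0, 1)")
            if v >= self.base_transmittance:
                raise ConfigurationError(f"{name} must be < base_transmittance")
        if self.itcz_width <= 0 or self.storm_track_width <= 0 or self.correlation_length <= 0:
            raise ConfigurationError("width and correlation-length parameters must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 < self.high_lat_onset < LAT_MAX:
            raise ConfigurationError("high_lat_onset must be inside (0, 70)")


@dataclass
class StationSeries:
    """Monthly PAR series at a point site (W m^-2).

    ``monthly_par`` has columns year, month, par_wm2 with unique
    (year, month) pairs.
    """

    site_id: str
    lat: float
    lon: float
    monthly_par: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.monthly_par, columns=["year", "month", "par_wm2"])
        if df.duplicated(["year", "month"]).any():
            raise ConfigurationError("months must be unique per year")
        if (df["par_wm2"] < 0).any():
            raise ConfigurationError("station PAR must be >= 0")
        self.monthly_par = df.reset_index(drop=True)


def transmittance_profile(params: CloudModelParams, latitude, day_of_year: int):
    """Deterministic latitude/season transmittance profile (noise-free).

    base minus three depressions: a Gaussian ITCZ cloud band (centered just
    north of the equator), non-seasonal mid-latitude storm-track bands in
    both hemispheres, and a high-latitude winter depression that ramps up
    poleward of ``high_lat_onset`` with a cosine annual cycle peaking at the
    local winter solstice.  The combination reproduces the qualitative CF
    geography the pipeline is meant to recover: depressed transmittance at
    the equator, the global maximum in the southern subtropics near 20 deg S
    (the ITCZ sits north of the equator, so the southern subtropical clear
    belt is wider), and strong boreal-winter attenuation above 40 deg N.
    """
    lat = np.asarray(latitude, dtype=float)
    itcz = params.itcz_depth * np.exp(
        -0.5 * ((lat - params.itcz_center_lat) / params.itcz_width) ** 2
    )
    storm = params.storm_track_depth * np.exp(
        -0.5 * ((np.abs(lat) - params.storm_track_center) / params.storm_track_width) ** 2
    )
    w_n = 0.5 * (1 + np.cos(2 * np.pi * (day_of_year - _NH_WINTER_SOLSTICE_DOY) / 365.25))
    w_s = 0.5 * (1 + np.cos(2 * np.pi * (day_of_year - _SH_WINTER_SOLSTICE_DOY) / 365.25))
    ramp = np.clip((np.abs(lat) - params.high_lat_onset) / (LAT_MAX - params.high_lat_onset), 0, 1)
    seasonal = params.high_lat_winter_depth * ramp * np.where(lat >= 0, w_n, w_s)
    return np.clip(params.base_transmittance - itcz - storm - seasonal, 1e-6, 1.0)


def _correlated_standard_field(shape, corr_cells_y, corr_cells_x, rng) -> np.ndarray:
    """Zero-mean unit-variance Gaussian field with an exponential correlogram,
    synthesised spectrally (2-D exponential covariance has power spectrum
    proportional to (1 + (kL)^2)^(-3/2))."""
    ny, nx = shape
    ky = np.fft.fftfreq(ny)[:, None] * 2 * np.pi
    kx = np.fft.fftfreq(nx)[None, :] * 2 * np.pi
    k2 = (ky * corr_cells_y) ** 2 + (kx * corr_cells_x) ** 2
    amp = (1.0 + k2) ** -0.75
    white = rng.standard_normal(shape)
    f = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
    # white noise through a Fourier filter has variance mean(amp^2)
    return f / np.sqrt(np.mean(amp**2))


def _day_rng(params: CloudModelParams, day_of_year: int) -> np.random.Generator:
    return np.random.default_rng((params.seed + day_of_year) % _SEED_MOD)


def simulate_transmittance_field(params: CloudModelParams, grid: GridSpec,
                                 day_of_year: int) -> np.ndarray:
    """One day's cloud-transmittance field on a grid, every cell in (0, 1].

    The field is the deterministic profile times a spatially correlated
    lognormal noise field with median 1 (log-sd = ``noise_sd``), so its
    expected value at a latitude tracks the deterministic profile.  Fields
    are reproducible: the RNG is seeded with ``seed + day_of_year``, making
    distinct days independent and repeated calls bit-identical.
    """
    if not 1 <= day_of_year <= 366:
        raise ConfigurationError("day_of_year must be in 1..366")
    profile = transmittance_profile(params, grid.lat, day_of_year)[:, None]
    field = np.broadcast_to(profile, grid.shape).copy()
    if params.noise_sd > 0:
        dlat = abs(float(np.diff(grid.lat).mean()))
        dlon = abs(float(np.diff(grid.lon).mean())) if grid.lon.size > 1 else dlat
        z = _correlated_standard_field(
            grid.shape, params.correlation_length / dlat,
            params.correlation_length / dlon, _day_rng(params, day_of_year),
        )
        field = field * np.exp(params.noise_sd * z)
    return np.clip(field, 1e-6, 1.0)


def monthly_mean_transmittance(params: CloudModelParams, grid: GridSpec,
                               days: Iterable[int], realized: bool = True,
                               weights: Sequence[np.ndarray] | None = None) -> np.ndarray:
    """Mean transmittance over a set of days of year.

    With ``realized=True`` (default) this is the mean of the noisy daily
    fields actually applied by the simulators — the quantity a monthly CF
    estimates.  With ``realized=False`` it is the mean of the deterministic
    noise-free profile, the target of the long-run convergence property.

    ``weights`` (one array or scalar per day, e.g. daily clear-sky PAR)
    switches from the plain day mean to an irradiance-weighted mean.  A
    monthly CF is a ratio of monthly-mean PAR values, so it estimates the
    *daylight-weighted* monthly transmittance; the two means differ
    noticeably only where clear-sky PAR changes strongly within the month
    (winter high latitudes).
    """
    days = list(days)
    if realized:
        stack = [simulate_transmittance_field(params, grid, d) for d in days]
    else:
        stack = [
            np.broadcast_to(
                transmittance_profile(params, grid.lat, d)[:, None], grid.shape
            )
            for d in days
        ]
    if weights is None:
        return np.mean(stack, axis=0)
    if len(weights) != len(days):
        raise ConfigurationError("need one weight (scalar or field) per day")
    num = np.zeros(grid.shape)
    den = np.zeros(grid.shape)
    for t, w in zip(stack, weights):
        w = np.broadcast_to(np.asarray(w, dtype=float), grid.shape)
        num += w * t
        den += w
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _apply_mask(values: np.ndarray, grid: GridSpec, want_land: bool) -> np.ndarray:
    if grid.land_mask is None:
        return values
    out = values.copy()
    out[grid.land_mask != want_land] = np.nan
    return out


def simulate_land_par(clear_sky: Sequence[PARGrid], params: CloudModelParams) -> list[PARGrid]:
    """Land-style real-sky product: 3-hourly energy-units grids, land cells only.

    Each output is the input clear-sky grid times the day's transmittance
    field (all 3-h slots of one day share that day's field).
    """
    out = []
    for grid in clear_sky:
        if grid.units != "energy":
            raise UnitsError("land-style simulation requires energy-units clear-sky input")
        t_field = simulate_transmittance_field(params, grid.grid, grid.time.dayofyear)
        values = _apply_mask(grid.values * t_field, grid.grid, want_land=True)
        out.append(grid.copy_with(values=values, provenance="real_sky_land"))
    return out


def simulate_ocean_par(clear_sky_daily: Sequence[PARGrid], params: CloudModelParams) -> list[PARGrid]:
    """Ocean-style real-sky product: daily quantum-units grids, ocean cells only."""
    out = []
    for grid in clear_sky_daily:
        if grid.units != "energy":
            raise UnitsError("ocean-style simulation expects energy-units clear-sky input")
        t_field = simulate_transmittance_field(params, grid.grid, grid.time.dayofyear)
        values = _apply_mask(
            energy_to_quantum(grid.values * t_field), grid.grid, want_land=False
        )
        out.append(
            grid.copy_with(values=values, units="quantum", provenance="real_sky_ocean")
        )
    return out


def simulate_station_par(site_id: str, lat: float, lon: float,
                         clear_sky_monthly: Sequence[float],
                         params: CloudModelParams, grid: GridSpec,
                         year: int = 2020) -> StationSeries:
    """Monthly station series consistent with the gridded simulation.

    For each month, station PAR = clear-sky monthly PAR at the site times the
    month's mean realized transmittance at the station's grid cell — the same
    daily fields (same seed) the gridded simulators apply, so with
    within-month-constant clear sky the station series equals the co-located
    grid-cell series exactly.
    """
    if not LAT_MIN <= lat <= LAT_MAX:
        raise ConfigurationError(f"station latitude must be in [{LAT_MIN}, {LAT_MAX}]")
    clear = list(clear_sky_monthly)
    if len(clear) != 12:
        raise ConfigurationError("clear_sky_monthly must have 12 values (Jan..Dec)")
    i, j = grid.nearest_cell(lat, lon)
    rows = []
    for month, clear_par in zip(range(1, 13), clear):
        start = pd.Timestamp(year, month, 1)
        days = pd.date_range(start, start + pd.offsets.MonthEnd(0), freq="D").dayofyear
        t_bar = np.mean(
            [simulate_transmittance_field(params, grid, int(d))[i, j] for d in days]
        )
        rows.append({"year": year, "month": month, "par_wm2": clear_par * t_bar})
    return StationSeries(site_id=site_id, lat=lat, lon=lon, monthly_par=pd.DataFrame(rows))


def stations_to_csv(stations: Sequence[StationSeries], path) -> None:
    """Write station series as CSV (site_id, lat, lon, year, month, par_wm2)."""
    frames = []
    for s in stations:
        df = s.monthly_par.copy()
        df.insert(0, "lon", s.lon)
        df.insert(0, "lat", s.lat)
        df.insert(0, "site_id", s.site_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def stations_from_csv(path) -> list[StationSeries]:
    df = pd.read_csv(path)
    out = []
    for site_id, g in df.groupby("site_id", sort=False):
        out.append(
            StationSeries(
                site_id=str(site_id), lat=float(g["lat"].iloc[0]),
                lon=float(g["lon"].iloc[0]),
                monthly_par=g[["year", "month", "par_wm2"]],
            )
        )
    return out


def write_grids(grids: Sequence[PARGrid], out_dir) -> list[Path]:
    """Write one ASCII-grid file per timestep into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for g in grids:
        stamp = g.time.strftime("%Y%m%dT%H" if g.freq == "3h" else "%Y%m%d")
        p = out_dir / f"{g.provenance}_{stamp}.asc"
        write_ascii_grid(p, g)
        paths.append(p)
    return paths
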