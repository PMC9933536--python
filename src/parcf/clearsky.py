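"""Clear-sky PAR model and the latitude-polynomial interpolation.

The clear-sky reference here is deliberately simple: a solar-geometry
calculation (declination + hour angle) driving a broadband airmass
attenuation law,

    PAR(t) = S_PAR * tau ** (1 / max(cos θ_z, ε)) * cos θ_z,

where ``S_PAR`` is the PAR portion of the solar constant, ``tau`` a
broadband clear-sky transmittance and θ_z the solar zenith angle.  It is a
stand-in for a full radiative-transfer spectral model: anything better
(e.g. SMARTS output) can be substituted through
:func:`parcf.spectra.read_external_spectrum` or an externally supplied
monthly PAR table, and every downstream stage is agnostic to the source.

Hourly values are averaged (nighttime zeros included) into daily and
calendar-month means, and monthly means sampled every 5 degrees of latitude
are interpolated to arbitrary latitudes with a least-squares fourth-order
polynomial, mirroring the coarse-to-fine workflow used to put a clear-sky
value under every satellite pixel.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .grids import LAT_MAX, LAT_MIN
from .spectra import DELTA_LAMBDA_NM, WAVELENGTHS_NM, Spectrum

#: floor on cos(zenith) in the airmass exponent (grazing-sun guard)
EPS_AIRMASS = 0.02

#: PAR fraction (~39%) of the 1361 W m^-2 total solar constant
DEFAULT_SOLAR_CONSTANT_PAR = 531.0


def _default_spectral_shape() -> np.ndarray:
    """Flat per-nm weights over 400-700 nm with a linear UV tail to zero at
    300 nm, normalised so the 400-700 nm rectangle sum is exactly 1."""
    w = np.ones_like(WAVELENGTHS_NM)
    uv = WAVELENGTHS_NM < 400.0
    w[uv] = (WAVELENGTHS_NM[uv] - 300.0) / 100.0
    par_sum = w[WAVELENGTHS_NM >= 400.0].sum() * DELTA_LAMBDA_NM
    return w / par_sum


@dataclass(frozen=True)
class SolarGeometry:
    """Sun position for one latitude / day / solar hour."""

    day_of_year: int
    latitude: float
    solar_hour: float
    declination: float  # degrees
    cos_zenith: float  # clamped to [0, 1] for irradiance use


@dataclass
class ClearSkyParams:
    """Tunables of the broadband clear-sky model."""

    solar_constant_par: float = DEFAULT_SOLAR_CONSTANT_PAR  # W m^-2
    broadband_transmittance: float = 0.75  # dimensionless, (0, 1]
    spectral_shape: np.ndarray = field(default_factory=_default_spectral_shape)

    def __post_init__(self):
        if not 0 < self.broadband_transmittance <= 1:
            raise ConfigurationError("broadband_transmittance must be in (0, 1]")
        if self.solar_constant_par <= 0:
            raise ConfigurationError("solar_constant_par must be positive")
        shape = np.asarray(self.spectral_shape, dtype=float)
        if shape.shape != WAVELENGTHS_NM.shape or np.any(shape < 0):
            raise ConfigurationError("spectral_shape must be non-negative on the 300-700 nm grid")
        par_sum = shape[WAVELENGTHS_NM >= 400.0].sum() * DELTA_LAMBDA_NM
        if not np.isclose(par_sum, 1.0, rtol=1e-6):
            raise ConfigurationError("spectral_shape must integrate to 1 over 400-700 nm")
        self.spectral_shape = shape


def declination_deg(day_of_year: int) -> float:
    """Solar declination (degrees) from the standard Cooper approximation."""
    return 23.45 * np.sin(2.0 * np.pi * (284 + day_of_year) / 365.0)


def solar_position(day_of_year: int, latitude: float, solar_hour: float) -> SolarGeometry:
    """Sun geometry at a latitude for a (solar-time) hour of a day of year.

    cos θ_z = sin φ sin δ + cos φ cos δ cos h with h the hour angle from
    solar noon; negative values (sun below horizon) are clamped to 0.
    """
    if not 1 <= day_of_year <= 366:
        raise ConfigurationError("day_of_year must be in 1..366")
    if not -90 <= latitude <= 90:
        raise ConfigurationError("latitude must be in [-90, 90]")
    if not 0 <= solar_hour <= 24:
        raise ConfigurationError("solar_hour must be in [0, 24]")
    decl = declination_deg(day_of_year)
    phi, delta = np.radians(latitude), np.radians(decl)
    hour_angle = np.radians(15.0 * (solar_hour - 12.0))
    cosz = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(hour_angle)
    return SolarGeometry(
        day_of_year=day_of_year, latitude=latitude, solar_hour=solar_hour,
        declination=float(decl), cos_zenith=float(np.clip(cosz, 0.0, 1.0)),
    )


def clearsky_par_hourly(geom: SolarGeometry, params: ClearSkyParams | None = None) -> float:
    """Instantaneous clear-sky PAR (W m^-2) for one sun geometry."""
    params = params or ClearSkyParams()
    cosz = geom.cos_zenith
    if cosz <= 0.0:
        return 0.0
    airmass = 1.0 / max(cosz, EPS_AIRMASS)
    return params.solar_constant_par * params.broadband_transmittance**airmass * cosz


_HOUR_CENTERS = np.arange(24) + 0.5


def clearsky_par_day(latitude: float, day_of_year: int,
                     params: ClearSkyParams | None = None) -> float:
    """Daily mean clear-sky PAR (W m^-2), nighttime zeros included."""
    params = params or ClearSkyParams()
    vals = [
        clearsky_par_hourly(solar_position(day_of_year, latitude, h), params)
        for h in _HOUR_CENTERS
    ]
    return float(np.mean(vals))


def clearsky_par_period(latitude: float, period: str, params: ClearSkyParams | None = None,
                        *, day_of_year: int | None = None, month: int | None = None,
                        leap: bool = False) -> float:
    """Average clear-sky PAR (W m^-2) over a day or a calendar month.

    Monthly averages are the plain mean of the month's daily averages (so
    the hourly -> daily -> monthly chain is exactly mean-preserving); the
    calendar is leap-aware via ``leap``.
    """
    if not LAT_MIN <= latitude <= LAT_MAX:
        raise ConfigurationError(f"latitude must be in [{LAT_MIN}, {LAT_MAX}]")
    params = params or ClearSkyParams()
    if period == "day":
        if day_of_year is None:
            raise ConfigurationError("day_of_year required for period='day'")
        return clearsky_par_day(latitude, day_of_year, params)
    if period == "month":
        if month is None:
            raise ConfigurationError("month required for period='month'")
        year = 2020 if leap else 2019  # representative non-leap / leap calendars
        start = pd.Timestamp(year, month, 1).dayofyear
        ndays = calendar.monthrange(year, month)[1]
        days = range(start, start + ndays)
        return float(np.mean([clearsky_par_day(latitude, d, params) for d in days]))
    raise ConfigurationError(f"unknown period {period!r}")


def clearsky_spectrum(geom: SolarGeometry, params: ClearSkyParams | None = None) -> Spectrum:
    """Clear-sky spectral irradiance (W m^-2 nm^-1, 300-700 nm).

    The broadband PAR value is distributed over wavelength by the normalised
    spectral shape, so the spectrum's 400-700 nm integral equals
    :func:`clearsky_par_hourly` exactly and scaling the broadband value
    scales every spectral sample linearly.
    """
    params = params or ClearSkyParams()
    broadband = clearsky_par_hourly(geom, params)
    return Spectrum(params.spectral_shape * broadband, units="energy")


# ---------------------------------------------------------------------------
# latitude-polynomial interpolation of monthly clear-sky PAR


@dataclass
class LatPolyFit:
    """Degree-4 least-squares polynomial of monthly clear-sky PAR vs latitude.

    Evaluation outside ``fit_domain`` raises; negative predictions are
    floored at 0 (polar-winter tails of the polynomial).
    """

    month: int
    coefficients: np.ndarray  # c0..c4, ascending powers of latitude
    fit_domain: tuple[float, float] = (LAT_MIN, LAT_MAX)
    rmse: float = 0.0

    def __call__(self, latitude):
        lat = np.asarray(latitude, dtype=float)
        lo, hi = self.fit_domain
        if np.any(lat < lo - 1e-9) or np.any(lat > hi + 1e-9):
            raise ConfigurationError(
                f"latitude outside fit domain [{lo}, {hi}]"
            )
        pred = np.polynomial.polynomial.polyval(lat, self.coefficients)
        pred = np.maximum(pred, 0.0)
        return float(pred) if np.isscalar(latitude) else pred

    def to_row(self) -> dict:
        c = self.coefficients
        return {"month": self.month, **{f"c{i}": c[i] for i in range(5)}, "rmse": self.rmse}


def fit_latitude_polynomial(latitudes, par_values, month: int) -> LatPolyFit:
    """Least-squares degree-4 fit of monthly clear-sky PAR against latitude.

    Needs at least 5 distinct latitude samples (the paper-style input is a
    5-degree grid).  The stored rmse is the in-sample root-mean-square
    residual.
    """
    lat = np.asarray(latitudes, dtype=float)
    par = np.asarray(par_values, dtype=float)
    if lat.shape != par.shape or lat.ndim != 1:
        raise ConfigurationError("latitudes and PAR values must be matching 1-D arrays")
    if np.unique(lat).size < 5:
        raise ConfigurationError("need >= 5 distinct latitudes for a degree-4 fit")
    coeffs = np.polynomial.polynomial.polyfit(lat, par, deg=4)
    resid = np.polynomial.polynomial.polyval(lat, coeffs) - par
    return LatPolyFit(
        month=month, coefficients=coeffs,
        fit_domain=(float(lat.min()), float(lat.max())),
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


def monthly_latitude_table(params: ClearSkyParams | None = None, lat_step: float = 5.0,
                           months=range(1, 13), leap: bool = False) -> pd.DataFrame:
    """Monthly clear-sky PAR on a latitude grid; columns month, latitude, par_wm2."""
    params = params or ClearSkyParams()
    lats = np.arange(LAT_MIN, LAT_MAX + lat_step / 2, lat_step)
    rows = [
        {"month": m, "latitude": lat,
         "par_wm2": clearsky_par_period(lat, "month", params, month=m, leap=leap)}
        for m in months for lat in lats
    ]
    return pd.DataFrame(rows)


def fit_all_months(table: pd.DataFrame) -> dict[int, LatPolyFit]:
    """Fit one latitude polynomial per month from a monthly_latitude_table."""
    return {
        int(m): fit_latitude_polynomial(g["latitude"].to_numpy(), g["par_wm2"].to_numpy(), int(m))
        for m, g in table.groupby("month")
    }


def fits_to_csv(fits: dict[int, LatPolyFit], path) -> None:
    pd.DataFrame([f.to_row() for f in fits.values()]).to_csv(path, index=False)


def fits_from_csv(path) -> dict[int, LatPolyFit]:
    df = pd.read_csv(path)
    return {
        int(r["month"]): LatPolyFit(
            month=int(r["month"]),
            coefficients=np.array([r[f"c{i}"] for i in range(5)]),
            rmse=float(r["rmse"]),
        )
        for _, r in df.iterrows()
    }
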