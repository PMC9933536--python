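"""Wavelength-resolved direct photolysis in surface waters.

The depth-averaged first-order rate constant for direct photolysis of a
dissolved compound is

    k_dir = ln(10) * sum_lambda I0_l * eps_l * phi_l * S(Kd_l, z) * dl   [s^-1]

with I0_l the incident irradiance in mmol photons cm^-2 s^-1 nm^-1, eps_l
the molar absorptivity (M^-1 cm^-1), phi_l the quantum yield
(mol / mol photons), and S the light-screening factor

    S = (1 - 10^(-Kd_l * z)) / (ln(10) * Kd_l * z)

for a water column of depth z (cm) with decadic diffuse attenuation Kd_l
(cm^-1).  The unit bookkeeping is exact: mmol -> mol (1e-3) cancels the
litre -> cm^3 factor (1e3) hiding in the molar absorptivity, so the sum is
s^-1 with no further constants.  The compound's own contribution to Kd is
assumed negligible next to dissolved organic matter.

For an acid with pKa near ambient pH only the deprotonated (phenolate)
form photolyses appreciably; the apparent rate constant multiplies k_dir of
the phenolate by its Henderson–Hasselbalch fraction, and the half-life is
ln 2 / k.  A monthly depth schedule (deep holomictic mixing in winter,
shallow epilimnion when stratified) and a CF time series turn these
per-spectrum rates into annual averages and seasonal distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, GridMismatchError
from .grids import season_of_month
from .spectra import DELTA_LAMBDA_NM, WAVELENGTHS_NM, Spectrum, resample_to_grid

LN10 = float(np.log(10.0))

SECONDS_PER_DAY = 86400.0

_SERIES_CUTOFF = 1e-6  # kd*z below which the screening factor uses its series


def screening_factor(kd, z: float = 1.0):
    """Depth-averaged light-screening factor S = (1 - 10^(-Kd z)) / (ln10 Kd z).

    With the default ``z = 1`` the first argument is read directly as the
    dimensionless decadic optical depth Kd*z.

    S is the fraction of the incident photon flux available on average over
    a column of depth ``z`` relative to the optically thin limit: S -> 1 as
    Kd z -> 0 (evaluated by series expansion below 1e-6 to avoid
    cancellation) and decreases strictly with Kd z.
    """
    kd = np.asarray(kd, dtype=float)
    if np.any(kd < 0):
        raise ConfigurationError("Kd must be >= 0")
    if z <= 0:
        raise ConfigurationError("depth z must be > 0")
    u = kd * z * LN10  # natural-log optical depth
    small = u < _SERIES_CUTOFF * LN10
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(small, 1.0 - u / 2.0 + u**2 / 6.0, -np.expm1(-u) / np.where(u == 0, 1.0, u))
    return float(s) if np.isscalar(z) and s.ndim == 0 else s


@dataclass
class KdModel:
    """Power-law attenuation model Kd_l = a_l * DOC^b_l + baseline_l (cm^-1).

    Coefficients follow the DOC-driven attenuation parameterisations used
    in lake optics; they are site- and study-specific and must be supplied
    by the user (scalars broadcast over the wavelength grid).
    """

    a: np.ndarray | float
    b: np.ndarray | float
    baseline: np.ndarray | float = 0.0

    def __call__(self, doc: float) -> np.ndarray:
        if doc < 0:
            raise ConfigurationError("DOC must be >= 0")
        a = np.broadcast_to(np.asarray(self.a, dtype=float), WAVELENGTHS_NM.shape)
        b = np.broadcast_to(np.asarray(self.b, dtype=float), WAVELENGTHS_NM.shape)
        base = np.broadcast_to(np.asarray(self.baseline, dtype=float), WAVELENGTHS_NM.shape)
        with np.errstate(divide="ignore"):
            kd = a * np.power(doc, b) + base if doc > 0 else base.copy()
        if np.any(kd < 0):
            raise ConfigurationError("Kd model produced negative attenuation")
        return np.asarray(kd, dtype=float)


def kd_from_doc(doc: float, kd_model: KdModel) -> np.ndarray:
    """Diffuse attenuation table on the wavelength grid from a DOC level."""
    if kd_model is None:
        raise ConfigurationError(
            "no Kd coefficients supplied; provide a KdModel (a, b, baseline) "
            "or an explicit Kd table for the waterbody"
        )
    return kd_model(doc)


@dataclass
class Compound:
    """Photochemical identity of a dissolved contaminant.

    ``epsilon`` (M^-1 cm^-1) and ``quantum_yield`` (mol per mol photons) live
    on the shared 300-700 nm grid; a scalar quantum yield broadcasts.
    """

    epsilon: np.ndarray
    quantum_yield: np.ndarray | float
    pka: float | None = None
    species_label: str = ""

    def __post_init__(self):
        eps = np.asarray(self.epsilon, dtype=float)
        if eps.shape != WAVELENGTHS_NM.shape:
            raise GridMismatchError("epsilon must be on the 1 nm 300-700 nm grid")
        if np.any(eps < 0):
            raise ConfigurationError("molar absorptivity must be >= 0")
        phi = np.broadcast_to(np.asarray(self.quantum_yield, dtype=float),
                              WAVELENGTHS_NM.shape).copy()
        if np.any((phi < 0) | (phi > 1)):
            raise ConfigurationError("quantum yield must be within [0, 1]")
        self.epsilon = eps
        self.quantum_yield = phi

    @classmethod
    def from_tables(cls, eps_wavelength_nm, eps_values, phi, pka=None,
                    species_label="") -> "Compound":
        """Build from an arbitrary-grid absorptivity table and a scalar or
        tabulated quantum yield (interpolated onto the package grid)."""
        eps = resample_to_grid(eps_wavelength_nm, eps_values)
        if np.ndim(phi) > 0 and not np.isscalar(phi):
            phi = np.asarray(phi, dtype=float)
            if phi.shape != WAVELENGTHS_NM.shape:
                raise GridMismatchError("tabulated quantum yield must be on the package grid")
        return cls(epsilon=eps, quantum_yield=phi, pka=pka, species_label=species_label)


#: Greifensee-style mixing schedule: holomictic full-depth mixing December
#: through March, stratified with a shallow epilimnion the rest of the year.
def two_depth_schedule(mixed_depth_cm: float, epilimnion_depth_cm: float,
                       mixed_months=(12, 1, 2, 3)) -> dict[int, float]:
    return {
        m: (mixed_depth_cm if m in mixed_months else epilimnion_depth_cm)
        for m in range(1, 13)
    }


@dataclass
class WaterBody:
    """Lake optics and geometry for the photolysis calculation.

    ``kd_table`` (cm^-1 on the wavelength grid) takes precedence over the
    DOC-driven ``kd_model``.  ``kd_convention`` declares whether supplied
    attenuation values are decadic (default) or natural-log; natural-log
    input is divided by ln 10 on ingestion so all internal math is decadic.
    ``depth_schedule`` maps month (1-12) to the photic pathlength z in cm.
    """

    ph: float
    doc: float = 0.0  # mg C L^-1
    kd_model: KdModel | None = None
    kd_table: np.ndarray | None = None
    depth_schedule: dict[int, float] = field(default_factory=dict)
    kd_convention: str = "decadic"

    def __post_init__(self):
        if self.kd_convention not in ("decadic", "natural"):
            raise ConfigurationError("kd_convention must be 'decadic' or 'natural'")
        if self.kd_table is not None:
            kd = np.asarray(self.kd_table, dtype=float)
            if kd.shape != WAVELENGTHS_NM.shape:
                raise GridMismatchError("kd_table must be on the 1 nm 300-700 nm grid")
            if self.kd_convention == "natural":
                kd = kd / LN10
            self.kd_table = kd
        for month, z in self.depth_schedule.items():
            if z <= 0:
                raise ConfigurationError(f"depth for month {month} must be > 0 cm")

    def kd(self) -> np.ndarray:
        """Decadic diffuse attenuation (cm^-1) on the wavelength grid."""
        if self.kd_table is not None:
            return self.kd_table
        kd = kd_from_doc(self.doc, self.kd_model)
        return kd / LN10 if self.kd_convention == "natural" else kd

    def depth_cm(self, month: int) -> float:
        if month not in self.depth_schedule:
            raise ConfigurationError(f"no depth scheduled for month {month}")
        return self.depth_schedule[month]


@dataclass
class RateResult:
    """Rate constants, half-life and the per-wavelength breakdown."""

    k_dir: float  # s^-1, phenolate (photolabile-form) rate constant
    k_app: float  # s^-1, speciation-corrected apparent rate constant
    half_life_days: float
    contributions: pd.DataFrame  # wavelength_nm, dk (s^-1 per 1 nm bin)


def k_direct(spectrum: Spectrum, compound: Compound, water: WaterBody | None,
             z: float | None = None, *, return_contributions: bool = False):
    """Depth-averaged direct-photolysis rate constant (s^-1).

    ``spectrum`` may carry energy or quantum units (converted internally to
    mmol photons cm^-2 s^-1 nm^-1).  With ``water=None`` or Kd*z in the
    optically thin limit the screening factor is 1 (surface rate).  The
    result is exactly linear in the spectrum, so applying a CF to the
    spectrum or to the returned k is equivalent.
    """
    irr = spectrum.to_quantum().irradiance
    if water is None:
        s_factor = 1.0
    else:
        if z is None:
            raise ConfigurationError("depth z (cm) required when a waterbody is given")
        s_factor = screening_factor(water.kd(), z)
    dk = LN10 * irr * compound.epsilon * compound.quantum_yield * s_factor * DELTA_LAMBDA_NM
    k = float(np.sum(dk))
    if return_contributions:
        return k, pd.DataFrame({"wavelength_nm": WAVELENGTHS_NM, "dk": dk})
    return k


def phenolate_fraction(ph: float, pka: float) -> float:
    """Henderson–Hasselbalch fraction of the deprotonated (phenolate) form,
    alpha = 1 / (1 + 10^(pKa - pH))."""
    return float(1.0 / (1.0 + 10.0 ** (pka - ph)))


def apparent_k(k_phenolate: float, ph: float, pka: float) -> float:
    """Apparent rate constant: phenolate k scaled by the phenolate fraction."""
    if k_phenolate < 0:
        raise ConfigurationError("rate constant must be >= 0")
    return k_phenolate * phenolate_fraction(ph, pka)


def half_life(k: float) -> float:
    """First-order half-life in days, t1/2 = ln 2 / k."""
    if k <= 0:
        raise ConfigurationError("half-life undefined for k <= 0")
    return float(np.log(2.0) / k / SECONDS_PER_DAY)


def rate_result(spectrum: Spectrum, compound: Compound, water: WaterBody,
                z: float) -> RateResult:
    """Full rate calculation for one spectrum: k_dir, k_app, half-life."""
    k, contrib = k_direct(spectrum, compound, water, z, return_contributions=True)
    k_app = apparent_k(k, water.ph, compound.pka) if compound.pka is not None else k
    return RateResult(
        k_dir=k, k_app=k_app,
        half_life_days=half_life(k_app) if k_app > 0 else float("inf"),
        contributions=contrib,
    )


def _days_in_month(year: int, month: int) -> int:
    import calendar

    return calendar.monthrange(year, month)[1]


def annual_average_k(monthly_spectra: Mapping[int, Spectrum], compound: Compound,
                     water: WaterBody, year: int = 2020,
                     apply_speciation: bool = True) -> float:
    """Day-count-weighted annual mean apparent rate constant (s^-1).

    Each month's k uses that month's scheduled depth (e.g. full mixed depth
    December-March, epilimnion depth otherwise); months are weighted by
    their day counts in ``year`` (leap-aware).
    """
    missing = [m for m in range(1, 13) if m not in monthly_spectra]
    if missing:
        raise ConfigurationError(f"missing monthly spectra for months {missing}")
    k_months, weights = [], []
    for month in range(1, 13):
        k = k_direct(monthly_spectra[month], compound, water, water.depth_cm(month))
        if apply_speciation and compound.pka is not None:
            k = apparent_k(k, water.ph, compound.pka)
        k_months.append(k)
        weights.append(_days_in_month(year, month))
    return float(np.average(k_months, weights=weights))


def _box_stats(values: np.ndarray) -> dict:
    """Tukey boxplot statistics: quartiles, median, whiskers at the most
    extreme data points within 1.5 x IQR of the box, and outliers beyond."""
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "q1": float(q1), "median": float(med), "q3": float(q3),
        "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
        "n_outliers": int(np.sum((values < lo_fence) | (values > hi_fence))),
        "n": int(values.size),
    }


def seasonal_rate_distributions(daily_spectra: Mapping, cf_series: Mapping,
                                compound: Compound, water: WaterBody,
                                surface: bool = True,
                                z: float | None = None) -> pd.DataFrame:
    """Seasonal boxplot statistics of daily rate constants, clear-sky vs
    CF-corrected.

    ``daily_spectra`` maps dates (anything pandas parses) to clear-sky
    spectra and ``cf_series`` maps the same dates to that day's CF.  In
    ``surface`` mode the optically thin limit (screening factor 1) is used;
    otherwise the depth ``z`` (cm) applies.  By linearity the corrected
    daily rate is the clear-sky rate scaled by the day's CF.  Returns one
    row per season x scenario with Tukey boxplot statistics.
    """
    records = []
    for day, spectrum in daily_spectra.items():
        if day not in cf_series:
            raise ConfigurationError(f"no CF for day {day}")
        if surface:
            k_clear = k_direct(spectrum, compound, None)
        else:
            k_clear = k_direct(spectrum, compound, water, z)
        if compound.pka is not None:
            k_clear = apparent_k(k_clear, water.ph, compound.pka)
        season = season_of_month(pd.Timestamp(day).month)
        records.append((season, k_clear, k_clear * float(cf_series[day])))
    if not records:
        raise ConfigurationError("no daily records supplied")
    df = pd.DataFrame(records, columns=["season", "k_clear", "k_corrected"])
    rows = []
    for season in ("DJF", "MAM", "JJA", "SON"):
        sub = df[df["season"] == season]
        if sub.empty:
            continue
        for scenario, col in (("clear_sky", "k_clear"), ("cf_corrected", "k_corrected")):
            rows.append(
                {"season": season, "scenario": scenario,
                 **_box_stats(sub[col].to_numpy())}
            )
    return pd.DataFrame(rows)
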