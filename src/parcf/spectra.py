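"""Wavelength-resolved irradiance on the package's fixed 300-700 nm grid.

Every spectral quantity in the package (irradiance, molar absorptivity,
quantum yield, diffuse attenuation) lives on the same 1 nm grid from 300 to
700 nm.  A spectral "integral" over a band is the rectangle sum
``sum(values) * 1 nm`` over the samples inside the band, a convention shared
by all modules so that normalisation contracts are exact.

Two unit systems are supported and tagged explicitly:

``energy``
    W m^-2 nm^-1, the natural output of a clear-sky irradiance model.
``quantum``
    mmol photons cm^-2 s^-1 nm^-1, the unit required by the photolysis
    rate-constant summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import SpectrumFormatError, UnitsError
from .units import photons_per_joule

#: shared wavelength grid, nm (401 samples, 1 nm spacing)
WAVELENGTHS_NM = np.arange(300.0, 701.0, 1.0)
DELTA_LAMBDA_NM = 1.0

_PAR_BAND = (WAVELENGTHS_NM >= 400.0) & (WAVELENGTHS_NM <= 700.0)

# W m^-2 nm^-1 -> mmol photons cm^-2 s^-1 nm^-1:
#   (mol m^-2 s^-1) * 1e3 mmol/mol / 1e4 cm^2/m^2
_ENERGY_TO_QUANTUM = photons_per_joule(WAVELENGTHS_NM) * 1e3 / 1e4


@dataclass
class Spectrum:
    """Spectral irradiance on the fixed 300-700 nm grid.

    Parameters
    ----------
    irradiance : ndarray, shape (401,)
        Spectral irradiance samples; must be non-negative.
    units : {"energy", "quantum"}
        ``energy`` = W m^-2 nm^-1; ``quantum`` = mmol photons cm^-2 s^-1 nm^-1.
    """

    irradiance: np.ndarray
    units: str = "energy"
    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS_NM.copy())

    def __post_init__(self):
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        if self.irradiance.shape != WAVELENGTHS_NM.shape:
            raise SpectrumFormatError(
                f"spectrum must have {WAVELENGTHS_NM.size} samples on the "
                f"1 nm 300-700 nm grid, got shape {self.irradiance.shape}"
            )
        if np.any(self.irradiance < 0):
            raise SpectrumFormatError("spectral irradiance must be non-negative")
        if self.units not in ("energy", "quantum"):
            raise UnitsError(f"unknown spectrum units {self.units!r}")

    def band_par(self) -> float:
        """Integral over the 400-700 nm PAR band (rectangle sum, Δλ = 1 nm)."""
        return float(np.sum(self.irradiance[_PAR_BAND]) * DELTA_LAMBDA_NM)

    def scale(self, factor: float) -> "Spectrum":
        """Return a copy scaled by a dimensionless factor (e.g. a CF)."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return Spectrum(self.irradiance * factor, units=self.units)

    def to_quantum(self) -> "Spectrum":
        """Convert to mmol photons cm^-2 s^-1 nm^-1 (wavelength-exact)."""
        if self.units == "quantum":
            return Spectrum(self.irradiance.copy(), units="quantum")
        return Spectrum(self.irradiance * _ENERGY_TO_QUANTUM, units="quantum")

    def to_energy(self) -> "Spectrum":
        """Convert to W m^-2 nm^-1 (wavelength-exact)."""
        if self.units == "energy":
            return Spectrum(self.irradiance.copy(), units="energy")
        return Spectrum(self.irradiance / _ENERGY_TO_QUANTUM, units="energy")


def read_external_spectrum(path, units: str = "energy") -> Spectrum:
    """Read a two-column text spectrum and resample to the package grid.

    The file must contain two whitespace- or comma-separated columns
    (wavelength in nm, spectral irradiance) with strictly increasing
    wavelengths and non-negative irradiance; lines starting with ``#`` are
    ignored.  Values are linearly interpolated onto the 1 nm 300-700 nm grid;
    wavelengths outside the file's coverage are set to 0.  This is the entry
    point for externally modeled reference spectra (e.g. SMARTS output).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectrumFormatError(f"cannot parse spectrum line: {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if len(rows) < 2:
        raise SpectrumFormatError("spectrum file needs at least two points")
    arr = np.asarray(rows, dtype=float)
    wl, irr = arr[:, 0], arr[:, 1]
    if np.any(np.diff(wl) <= 0):
        raise SpectrumFormatError("wavelengths must be strictly increasing")
    if np.any(irr < 0):
        raise SpectrumFormatError("irradiance values must be non-negative")
    resampled = np.interp(WAVELENGTHS_NM, wl, irr, left=0.0, right=0.0)
    # interp holds edge values flat; zero truly-outside wavelengths instead
    resampled[WAVELENGTHS_NM < wl[0]] = 0.0
    resampled[WAVELENGTHS_NM > wl[-1]] = 0.0
    return Spectrum(resampled, units=units)


def resample_to_grid(wavelength_nm, values) -> np.ndarray:
    """Linearly interpolate an arbitrary spectral table onto the fixed grid.

    Used for compound properties (molar absorptivity, quantum yield).
    Outside the table's coverage the value is held at 0.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    v = np.asarray(values, dtype=float)
    if wl.ndim != 1 or wl.shape != v.shape:
        raise SpectrumFormatError("wavelengths and values must be matching 1-D arrays")
    if np.any(np.diff(wl) <= 0):
        raise SpectrumFormatError("wavelengths must be strictly increasing")
    out = np.interp(WAVELENGTHS_NM, wl, v, left=0.0, right=0.0)
    out[WAVELENGTHS_NM < wl[0]] = 0.0
    out[WAVELENGTHS_NM > wl[-1]] = 0.0
    return out
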