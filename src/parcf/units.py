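"""Physical constants and PAR unit conversions.

Photosynthetically active radiation (PAR, 400-700 nm) circulates in two
unit systems: energy flux (W m^-2, the land-satellite and clear-sky-model
convention) and quantum flux (mol photon m^-2 day^-1, the ocean-satellite
convention).  The two are related through the energy carried by one mole of
photons at a reference wavelength; following common practice the spectral
mean of PAR is represented by ``LAMBDA_REF`` = 550 nm, the midpoint of the
PAR band.
"""

from __future__ import annotations

import numpy as np

from .exceptions import UnitsError

# CODATA 2018 exact values
PLANCK = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 2.99792458e8  # m s^-1
AVOGADRO = 6.02214076e23  # mol^-1

SECONDS_PER_DAY = 86400.0
LAMBDA_REF_NM = 550.0

#: energy of one mole of photons at the reference wavelength, J mol^-1
J_PER_MOL_PHOTON = AVOGADRO * PLANCK * SPEED_OF_LIGHT / (LAMBDA_REF_NM * 1e-9)

#: multiply mol photon m^-2 day^-1 by this to get W m^-2
QUANTUM_TO_ENERGY_FACTOR = J_PER_MOL_PHOTON / SECONDS_PER_DAY


def quantum_to_energy(par_quantum):
    """Convert quantum PAR (mol photon m^-2 day^-1) to energy PAR (W m^-2).

    The conversion is linear with a single factor derived from the Planck
    relation at the 550 nm band midpoint; :func:`energy_to_quantum` is its
    exact inverse.

    Raises
    ------
    UnitsError
        If any input value is negative (PAR is a non-negative flux).
    """
    q = np.asarray(par_quantum, dtype=float)
    if np.any(q[np.isfinite(q)] < 0):
        raise UnitsError("quantum PAR must be non-negative")
    out = q * QUANTUM_TO_ENERGY_FACTOR
    return float(out) if np.isscalar(par_quantum) else out


def energy_to_quantum(par_energy):
    """Convert energy PAR (W m^-2) to quantum PAR (mol photon m^-2 day^-1)."""
    e = np.asarray(par_energy, dtype=float)
    if np.any(e[np.isfinite(e)] < 0):
        raise UnitsError("energy PAR must be non-negative")
    out = e / QUANTUM_TO_ENERGY_FACTOR
    return float(out) if np.isscalar(par_energy) else out


def photons_per_joule(wavelength_nm):
    """Moles of photons per joule at each wavelength (mol J^-1)."""
    lam_m = np.asarray(wavelength_nm, dtype=float) * 1e-9
    return lam_m / (AVOGADRO * PLANCK * SPEED_OF_LIGHT)
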