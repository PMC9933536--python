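"""Shared fixtures: small grids, synthetic clear-sky stacks, toy compounds."""

import numpy as np
import pandas as pd
import pytest

from parcf import CloudModelParams, GridSpec, PARGrid
from parcf import clearsky as cs
from parcf.cf import aggregate_time
from parcf.spectra import WAVELENGTHS_NM, Spectrum


@pytest.fixture(scope="session")
def grid20():
    """20 x 24 global grid with the default longitude-band land mask."""
    return GridSpec.regular(nlat=20, nlon=24)


@pytest.fixture(scope="session")
def cloud_defaults():
    return CloudModelParams(seed=123)


@pytest.fixture(scope="session")
def clearsky_params():
    return cs.ClearSkyParams()


def build_clear_3h(grid, year, month, days, params=None):
    """3-hourly clear-sky PAR grids (slot centers 1.5h..22.5h) for given days."""
    params = params or cs.ClearSkyParams()
    slots = []
    for day in days:
        stamp = pd.Timestamp(year, month, day)
        for hour in np.arange(1.5, 24, 3.0):
            par = np.array(
                [cs.clearsky_par_hourly(cs.solar_position(stamp.dayofyear, lat, hour), params)
                 for lat in grid.lat]
            )
            slots.append(
                PARGrid(
                    values=np.repeat(par[:, None], grid.lon.size, axis=1),
                    grid=grid, units="energy",
                    time=stamp + pd.Timedelta(hours=hour), freq="3h",
                )
            )
    return slots


@pytest.fixture(scope="session")
def clear_june_10d(grid20):
    """Ten June days of 3-hourly clear-sky grids plus their daily means."""
    slots = build_clear_3h(grid20, 2020, 6, range(1, 11))
    daily = aggregate_time(slots, "daily")
    return slots, daily


def flat_quantum_spectrum(level=1e-6):
    """Flat spectrum in mmol photons cm^-2 s^-1 nm^-1 across 300-700 nm."""
    return Spectrum(np.full(WAVELENGTHS_NM.shape, level), units="quantum")


def uniform_grid(value, grid, **kwargs):
    """PARGrid with a constant value everywhere."""
    defaults = dict(units="energy", time=pd.Timestamp(2020, 6, 1), freq="M",
                    provenance="clear_sky")
    defaults.update(kwargs)
    return PARGrid(values=np.full(grid.shape, float(value)), grid=grid, **defaults)
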