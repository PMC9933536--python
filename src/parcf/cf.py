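"""Correction-factor pipeline: aggregation, land/ocean merge, CF statistics.

The correction factor (CF) at a cell and period is the ratio of real-sky to
clear-sky PAR,

    CF = PAR_real-sky / PAR_clear-sky,

a dimensionless multiplier in (0, ~1.2] that rescales a clear-sky reference
irradiance (or a full reference spectrum, clouds being spectrally neutral
over the PAR band) to expected real-sky conditions.  This module carries
gridded PAR from 3-hourly slots to daily, monthly and seasonal means,
merges the energy-units land product with the quantum-units ocean product,
forms CF rasters with a polar-night guard, and summarises CF distributions
the way the reference tables do: histogram modes, empirical 90% intervals,
interquartile ranges and per-cell inter-annual standard deviations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep

from .exceptions import ConfigurationError, GridMismatchError, UnitsError
from .grids import CFGrid, PARGrid, SEASON_MONTHS, season_of_month
from .units import quantum_to_energy

logger = logging.getLogger(__name__)

#: clear-sky floor (W m^-2) below which a CF is undefined (polar-night guard)
CLEAR_SKY_FLOOR_WM2 = 1.0

#: histogram bin width for mode estimation (matches 2-decimal table precision)
MODE_BIN_WIDTH = 0.01

#: relative land/ocean discrepancy that triggers a merge-conflict warning
MERGE_CONFLICT_RTOL = 0.05


# ---------------------------------------------------------------------------
# temporal aggregation


def _check_common_grid(grids: Sequence[PARGrid]):
    first = grids[0]
    for g in grids[1:]:
        if not g.grid.same_grid(first.grid):
            raise GridMismatchError("all grids must share the same lat/lon axes")
        if g.units != first.units:
            raise UnitsError("all grids must share the same units")


def _group_mean(grids: Sequence[PARGrid], keyfunc, freq: str,
                timefunc, season_func=None) -> list[PARGrid]:
    groups: dict = {}
    for g in grids:
        groups.setdefault(keyfunc(g), []).append(g)
    out = []
    for key in sorted(groups):
        members = groups[key]
        stack = np.stack([m.values for m in members])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(stack, axis=0)  # cells missing everywhere stay NaN
        out.append(
            members[0].copy_with(
                values=mean, freq=freq, time=timefunc(key),
                season=season_func(key) if season_func else None,
            )
        )
    return out


def aggregate_time(grids: Sequence[PARGrid], target: str) -> list[PARGrid]:
    """Average a sorted sequence of grids to daily, monthly or seasonal means.

    Per-cell arithmetic mean over the timesteps where the cell is present
    (a cell missing in some slots is averaged over the rest; a cell missing
    everywhere stays missing).  Season composites are the equal-weight mean
    of the three monthly grids (DJF = Dec, Jan, Feb etc.); December is
    assigned to the DJF of the following year.
    """
    if not grids:
        raise ConfigurationError("no grids to aggregate")
    _check_common_grid(grids)
    if target == "daily":
        return _group_mean(
            grids, lambda g: g.time.normalize(), "D", lambda key: key
        )
    if target == "monthly":
        return _group_mean(
            grids, lambda g: (g.time.year, g.time.month), "M",
            lambda key: pd.Timestamp(key[0], key[1], 1),
        )
    if target == "seasonal":
        def key(g):
            year = g.time.year + (1 if g.time.month == 12 else 0)
            return (year, ("DJF", "MAM", "JJA", "SON").index(season_of_month(g.time.month)))

        return _group_mean(
            grids, key, "seasonal",
            lambda k: pd.Timestamp(k[0], SEASON_MONTHS[("DJF", "MAM", "JJA", "SON")[k[1]]][-1], 1),
            season_func=lambda k: ("DJF", "MAM", "JJA", "SON")[k[1]],
        )
    raise ConfigurationError(f"unknown aggregation target {target!r}")


# ---------------------------------------------------------------------------
# land/ocean merge and CF computation


def merge_land_ocean(land: PARGrid, ocean: PARGrid) -> PARGrid:
    """Combine land and ocean products into one energy-units grid.

    The quantum-units ocean grid is converted to W m^-2 first.  Where both
    products are valid the land value wins; a relative discrepancy above
    ``MERGE_CONFLICT_RTOL`` is logged, never raised.
    """
    if not land.grid.same_grid(ocean.grid):
        raise GridMismatchError("land and ocean grids must share axes")
    if land.freq != ocean.freq:
        raise GridMismatchError("land and ocean grids must share the period")
    if land.units != "energy":
        raise UnitsError("land grid must carry energy units")
    ocean_energy = (
        ocean.values if ocean.units == "energy"
        else quantum_to_energy(np.where(np.isfinite(ocean.values), ocean.values, 0.0))
    )
    ocean_energy = np.where(np.isfinite(ocean.values), ocean_energy, np.nan)
    both = land.valid & np.isfinite(ocean_energy)
    if both.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.abs(land.values[both] - ocean_energy[both]) / np.maximum(
                ocean_energy[both], 1e-12
            )
        n_conflict = int(np.sum(rel > MERGE_CONFLICT_RTOL))
        if n_conflict:
            logger.warning(
                "merge_land_ocean: %d overlapping cells disagree by > %.0f%%; "
                "land values take precedence", n_conflict, 100 * MERGE_CONFLICT_RTOL,
            )
    merged = np.where(land.valid, land.values, ocean_energy)
    return land.copy_with(values=merged, units="energy", provenance="merged")


def compute_cf(real: PARGrid, clear, floor: float = CLEAR_SKY_FLOOR_WM2) -> CFGrid:
    """CF raster = real-sky / clear-sky PAR, masked below the clear-sky floor.

    ``clear`` may be a PARGrid on the same grid, a bare 2-D array of
    energy-units clear-sky PAR, or a :class:`~parcf.clearsky.LatPolyFit`
    evaluated on the grid's latitudes.  Cells where clear-sky PAR < ``floor``
    (polar night) or real-sky PAR is missing are masked.  CFs above 1 are
    retained; their frequency is logged.
    """
    if real.units != "energy":
        raise UnitsError("compute_cf requires energy-units real-sky PAR")
    if isinstance(clear, PARGrid):
        if clear.units != "energy":
            raise UnitsError("compute_cf requires energy-units clear-sky PAR")
        if not clear.grid.same_grid(real.grid):
            raise GridMismatchError("real and clear grids must share axes")
        clear_values = clear.values
    elif callable(clear):  # latitude polynomial
        clear_values = np.broadcast_to(
            np.asarray(clear(real.grid.lat), dtype=float)[:, None], real.grid.shape
        )
    else:
        clear_values = np.asarray(clear, dtype=float)
        if clear_values.shape != real.grid.shape:
            raise GridMismatchError("clear-sky array shape must match the grid")
    mask = real.valid & np.isfinite(clear_values) & (clear_values >= floor)
    values = np.full(real.grid.shape, np.nan)
    values[mask] = real.values[mask] / clear_values[mask]
    cf = CFGrid(
        values=values, mask=mask, grid=real.grid, freq=real.freq,
        time=real.time, season=real.season, years_included=(real.time.year,),
    )
    frac = cf.fraction_above_one()
    if frac:
        logger.info("compute_cf: %.2f%% of valid CFs exceed 1 (retained)", 100 * frac)
    return cf


# ---------------------------------------------------------------------------
# distribution statistics


def cf_mode(values) -> float:
    """Histogram mode of a CF sample: bin width 0.01 over [0, max], mode =
    center of the highest-count bin, ties broken toward the higher bin.

    The mode, not the mean, is the representative value because CF
    distributions are typically skewed and multi-modal.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ConfigurationError("cf_mode needs a non-empty sample")
    # bins [0, 0.01), [0.01, 0.02), ...; a value at a bin edge opens the
    # higher bin (0.80 -> center 0.805), with a 1e-9 guard against float
    # representation pushing 0.70 just below its edge
    idx = np.floor(v / MODE_BIN_WIDTH + 1e-9).astype(int)
    counts = np.bincount(idx)
    best = counts.size - 1 - int(np.argmax(counts[::-1]))  # last argmax = higher bin
    return float((best + 0.5) * MODE_BIN_WIDTH)


def cf_ci90(values) -> tuple[float, float]:
    """Empirical 90% interval: the 5th and 95th percentiles of the sample
    (linear-interpolation quantile definition).  Needs n >= 20."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 20:
        raise ConfigurationError("cf_ci90 needs at least 20 values")
    lo, hi = np.percentile(v, [5.0, 95.0])
    return float(lo), float(hi)


def cf_iqr(values) -> float:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ConfigurationError("cf_iqr needs a non-empty sample")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    return float(q3 - q1)


def interannual_sd(cf_stack: Sequence[CFGrid]) -> np.ndarray:
    """Per-cell sample standard deviation of CFs across years.

    Only years where the cell is valid contribute; cells with fewer than two
    valid years are NaN.
    """
    if len(cf_stack) < 2:
        raise ConfigurationError("interannual_sd needs at least 2 years")
    first = cf_stack[0]
    for cf in cf_stack[1:]:
        if not cf.grid.same_grid(first.grid) or cf.freq != first.freq:
            raise GridMismatchError("CF stack must share grid and period type")
    stack = np.stack([np.where(cf.mask, cf.values, np.nan) for cf in cf_stack])
    n_valid = np.sum(np.isfinite(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sd[n_valid < 2] = np.nan
    return sd


def mean_cf(cf_stack: Sequence[CFGrid]) -> CFGrid:
    """Per-cell mean CF across years (the multi-year climatological CF)."""
    if not cf_stack:
        raise ConfigurationError("empty CF stack")
    first = cf_stack[0]
    stack = np.stack([np.where(cf.mask, cf.values, np.nan) for cf in cf_stack])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    years = tuple(sorted({y for cf in cf_stack for y in cf.years_included}))
    return CFGrid(
        values=mean, mask=np.isfinite(mean), grid=first.grid, freq=first.freq,
        time=first.time, season=first.season, years_included=years,
    )


# ---------------------------------------------------------------------------
# regional summaries


@dataclass
class RegionSpec:
    """A named region: either a lat/lon bounding box or a shapely polygon."""

    name: str
    lat_bounds: tuple[float, float] | None = None
    lon_bounds: tuple[float, float] | None = None
    polygon: object | None = None  # shapely geometry in lon/lat coordinates

    def cell_mask(self, grid) -> np.ndarray:
        if self.polygon is not None:
            prepared = prep(self.polygon)
            lat2d, lon2d = grid.lat2d, grid.lon2d
            mask = np.zeros(grid.shape, dtype=bool)
            for idx in np.ndindex(grid.shape):
                mask[idx] = prepared.contains(Point(lon2d[idx], lat2d[idx]))
            return mask
        if self.lat_bounds is None or self.lon_bounds is None:
            raise ConfigurationError(f"region {self.name!r} has no geometry")
        lat_ok = (grid.lat2d >= self.lat_bounds[0]) & (grid.lat2d <= self.lat_bounds[1])
        lon_ok = (grid.lon2d >= self.lon_bounds[0]) & (grid.lon2d <= self.lon_bounds[1])
        return lat_ok & lon_ok


@dataclass
class CFSummary:
    """Distribution summary of the CFs inside one region and season."""

    region: str
    season: str | None
    mode: float
    ci90: tuple[float, float]
    iqr: float
    n_cells: int


def regional_summary(cf: CFGrid, regions: Sequence[RegionSpec]) -> pd.DataFrame:
    """Mode / 90% interval / IQR / cell count of the CF distribution per region.

    Raises if a region does not intersect any valid cell, naming the region.
    Columns: region, season, mode, ci_low, ci_high, iqr, n_cells.
    """
    rows = []
    for region in regions:
        sel = region.cell_mask(cf.grid) & cf.mask
        vals = cf.values[sel]
        if vals.size == 0:
            raise ConfigurationError(
                f"region {region.name!r} has no valid CF cells on this grid"
            )
        lo, hi = cf_ci90(vals) if vals.size >= 20 else (float(vals.min()), float(vals.max()))
        rows.append(
            {
                "region": region.name, "season": cf.season,
                "mode": cf_mode(vals), "ci_low": lo, "ci_high": hi,
                "iqr": cf_iqr(vals), "n_cells": int(vals.size),
            }
        )
    return pd.DataFrame(rows)
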