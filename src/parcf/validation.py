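"""Station-based validation of the correction factors.

Directly measured monthly station PAR is compared to two predictions:
modeled clear-sky PAR at the station latitude, and the same clear-sky PAR
multiplied by the (multi-year mean) CF at the station's grid cell and
month.  An uncorrected clear-sky prediction systematically overestimates
measured PAR; a well-calibrated CF removes that bias.  The comparison is an
ordinary least-squares regression of measured on predicted, reported with
RMSE and mean bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .grids import CFGrid
from .synthetic import StationSeries

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    """OLS fit of measured on predicted PAR plus error metrics.

    ``mean_bias`` is the mean of (predicted - measured): positive when the
    prediction overestimates.
    """

    n: int
    slope: float
    intercept: float
    r_squared: float
    rmse: float  # W m^-2
    mean_bias: float  # W m^-2


def pair_station_predictions(
    stations: Sequence[StationSeries],
    clear_monthly: Mapping[str, Sequence[float]] | Sequence[float],
    cf_by_month: Mapping[int, CFGrid],
) -> pd.DataFrame:
    """Pair each station-month with its clear-sky and CF-corrected predictions.

    Parameters
    ----------
    stations :
        Measured monthly series.
    clear_monthly :
        12 clear-sky monthly PAR values (Jan..Dec, W m^-2) for all stations,
        or a mapping site_id -> 12 values.
    cf_by_month :
        Month -> CF raster (typically multi-year mean CFs).  Station-months
        falling in a masked cell are skipped with a log entry.

    Returns
    -------
    DataFrame with columns site_id, year, month, measured, clear, corrected.
    """
    rows = []
    for station in stations:
        clear = (
            clear_monthly[station.site_id]
            if isinstance(clear_monthly, Mapping) else clear_monthly
        )
        clear = list(clear)
        if len(clear) != 12:
            raise ConfigurationError("clear_monthly must provide 12 values per station")
        for _, rec in station.monthly_par.iterrows():
            month = int(rec["month"])
            if month not in cf_by_month:
                raise ConfigurationError(f"no CF grid for month {month}")
            cf = cf_by_month[month]
            i, j = cf.grid.nearest_cell(station.lat, station.lon)
            if not cf.mask[i, j]:
                logger.info(
                    "station %s month %d falls in a masked CF cell; skipped",
                    station.site_id, month,
                )
                continue
            clear_par = float(clear[month - 1])
            rows.append(
                {
                    "site_id": station.site_id, "year": int(rec["year"]),
                    "month": month, "measured": float(rec["par_wm2"]),
                    "clear": clear_par,
                    "corrected": clear_par * float(cf.values[i, j]),
                }
            )
    return pd.DataFrame(rows, columns=["site_id", "year", "month", "measured", "clear", "corrected"])


def regress(measured, predicted) -> ValidationReport:
    """OLS of measured on predicted with RMSE and mean bias of the prediction."""
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1:
        raise ConfigurationError("measured and predicted must be matching 1-D arrays")
    if m.size < 3:
        raise ConfigurationError("need at least 3 paired records")
    if np.ptp(p) == 0:
        raise ConfigurationError("zero-variance predictor; regression undefined")
    fit = stats.linregress(p, m)
    resid = p - m
    return ValidationReport(
        n=int(m.size), slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        rmse=float(np.sqrt(np.mean(resid**2))), mean_bias=float(np.mean(resid)),
    )


def validate(pairs: pd.DataFrame) -> dict[str, ValidationReport]:
    """Run the two-panel comparison: clear-sky and CF-corrected predictions."""
    return {
        "clear_sky": regress(pairs["measured"], pairs["clear"]),
        "cf_corrected": regress(pairs["measured"], pairs["corrected"]),
    }


def scatter_figure(pairs: pd.DataFrame, path=None):
    """Two-panel measured-vs-predicted scatter (clear-sky | CF-corrected)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4.2), sharex=True, sharey=True)
    lims = [0, max(pairs[["measured", "clear", "corrected"]].to_numpy().max() * 1.05, 1)]
    for ax, col, title in zip(axes, ["clear", "corrected"],
                              ["clear-sky PAR", "CF-corrected clear-sky PAR"]):
        ax.scatter(pairs[col], pairs["measured"], s=12, alpha=0.6)
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel(f"predicted ({title}), W m$^{{-2}}$")
        ax.set_xlim(lims), ax.set_ylim(lims)
    axes[0].set_ylabel("measured PAR, W m$^{-2}$")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
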