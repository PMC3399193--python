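"""Bioclimatic covariates from monthly climate series.

Six covariates drive all distribution models:

====  ==============================================  =====
name  meaning                                         units
====  ==============================================  =====
mat   annual mean temperature                         degC
ts    temperature seasonality, 100*sd(T)/mat          %
twp   max temperature of the warmest period           degC
ap    annual precipitation                            mm
ps    precipitation seasonality, 100*sd(P)/mean(P)    %
pdp   precipitation of the driest period              mm
====  ==============================================  =====

A "period" is a calendar month (the inputs are monthly surfaces); the
standard deviations are population standard deviations over the 12 periods.
Seasonality expressed as a percentage of the annual mean is undefined where
the annual mean temperature is not positive; those cells become nodata with
a warning.  An alternative convention (``sd_x100``, plain standard deviation
times 100) is available for parity with other bioclim toolchains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, MissingDataError, SchemaError
from .grids import GridSpec
from .synth import MonthlyClimateSeries

__all__ = ["BIOCLIM_VARS", "ClimateStack", "derive_bioclim", "window_average"]

BIOCLIM_VARS = ("mat", "ts", "twp", "ap", "ps", "pdp")


@dataclass
class ClimateStack:
    """The six bioclim rasters on a common grid."""

    mat: np.ndarray
    ts: np.ndarray
    twp: np.ndarray
    ap: np.ndarray
    ps: np.ndarray
    pdp: np.ndarray
    grid: GridSpec

    def layers(self) -> dict[str, np.ndarray]:
        return {v: getattr(self, v) for v in BIOCLIM_VARS}

    def valid_mask(self) -> np.ndarray:
        """Cells where every layer is finite."""
        m = np.ones(self.grid.shape, dtype=bool)
        for arr in self.layers().values():
            m &= np.isfinite(arr)
        return m

    def to_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Stack layers into an (n_cells, 6) matrix, restricted to ``mask``."""
        if mask is None:
            mask = self.valid_mask()
        return np.column_stack([getattr(self, v)[mask] for v in BIOCLIM_VARS])

    def to_array(self) -> np.ndarray:
        return np.stack([getattr(self, v) for v in BIOCLIM_VARS])

    @classmethod
    def from_array(cls, arr: np.ndarray, grid: GridSpec) -> "ClimateStack":
        if arr.shape != (6, *grid.shape):
            raise SchemaError(f"expected (6, rows, cols) array, got {arr.shape}")
        return cls(*(arr[i] for i in range(6)), grid=grid)


def derive_bioclim(
    series: MonthlyClimateSeries, ts_convention: str = "percent_of_mean"
) -> ClimateStack:
    """Derive the six bioclim covariates from one year of monthly climate."""
    if ts_convention not in ("percent_of_mean", "sd_x100"):
        raise InvalidParameterError(f"unknown ts_convention {ts_convention!r}")
    T = series.temperature
    P = series.precipitation
    mat = T.mean(axis=0)
    sd_t = T.std(axis=0)  # population sd over the 12 periods
    twp = T.max(axis=0)
    ap = P.sum(axis=0)
    mean_p = P.mean(axis=0)
    sd_p = P.std(axis=0)
    pdp = P.min(axis=0)

    if ts_convention == "sd_x100":
        ts = 100.0 * sd_t
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ts = np.where(mat > 0, 100.0 * sd_t / mat, np.nan)
        n_bad = int(np.sum(np.isfinite(mat) & (mat <= 0)))
        if n_bad:
            warnings.warn(
                f"temperature seasonality undefined at {n_bad} cells with "
                "non-positive annual mean temperature; set to nodata",
                stacklevel=2,
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(mean_p > 0, 100.0 * sd_p / mean_p, 0.0)
    ps = np.where(np.isfinite(mean_p), ps, np.nan)

    return ClimateStack(mat=mat, ts=ts, twp=twp, ap=ap, ps=ps, pdp=pdp, grid=series.grid)


def window_average(
    series_by_year: dict[int, MonthlyClimateSeries],
    center_year: int,
    half_window_years: int = 10,
) -> MonthlyClimateSeries:
    """Month-wise mean climate over a closed symmetric window of years.

    Each decade label in the projection series represents the mean climate
    of the years ``center - half .. center + half`` inclusive; every year in
    the window must be present.
    """
    years = list(range(center_year - half_window_years, center_year + half_window_years + 1))
    missing = [y for y in years if y not in series_by_year]
    if missing:
        raise MissingDataError(f"missing yearly series for window years: {missing}")
    grid = series_by_year[years[0]].grid
    temp = np.mean([series_by_year[y].temperature for y in years], axis=0)
    precip = np.mean([series_by_year[y].precipitation for y in years], axis=0)
    return MonthlyClimateSeries(
        temperature=temp, precipitation=precip, grid=grid, year_label=center_year
    )
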