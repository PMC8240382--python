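"""Window-specific bioclimatic variables from monthly climate stacks.

The variables follow the BIOCLIM naming but are computed over an arbitrary
month window rather than the calendar year, so that the same code serves the
annual analysis and the reproductive-season (May-July) analysis:

=========  =================================================================
BIO1       window mean temperature (degC); mean over months of (tmin+tmax)/2
BIO2       mean diurnal range (degC); mean over months of (tmax - tmin)
BIO3       isothermality (%); 100 * BIO2 / (max tmax - min tmin)
BIO4       temperature seasonality; 100 * sample SD of monthly mean temp
BIO6       minimum temperature of the coldest window month (degC)
BIO15      precipitation seasonality (CV %); 100 * SD / (1 + mean) of
           monthly precipitation (ANUCLIM +1 convention)
minTmax    minimum over window months of monthly maximum temperature (degC)
meanTmin   mean over window months of monthly minimum temperature (degC)
=========  =================================================================

SDs use ddof=1 (sample SD), the convention of the common bioclim toolchains.
BIO4 is kept on the SDx100 scale internally; divide by 100 for a
degrees-Celsius display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GeoGrid, MonthWindow, MonthlyClimateStack, write_raster

__all__ = [
    "BioclimSet",
    "derive_bioclim",
    "extract_at_points",
    "REPRODUCTIVE_VARS",
    "ANNUAL_VARS",
    "VARIABLE_CLASSES",
]

#: the seven covariates of the reproductive-period analysis
REPRODUCTIVE_VARS = ["BIO2", "BIO3", "BIO4", "BIO6", "BIO15", "minTmax", "meanTmin"]

#: the six non-redundant covariates of the annual analysis
ANNUAL_VARS = ["BIO1", "BIO2", "BIO3", "BIO4", "BIO6", "BIO15"]

#: hypothesis-relevant grouping: climatic-variability vs average-temperature
VARIABLE_CLASSES = {
    "BIO2": "variability",
    "BIO3": "variability",
    "BIO4": "variability",
    "BIO15": "variability",
    "BIO1": "average",
    "BIO6": "average",
    "minTmax": "average",
    "meanTmin": "average",
}


@dataclass
class BioclimSet:
    """Derived per-pixel climatic variables for one month window."""

    grid: GeoGrid
    window: MonthWindow
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    def matrix(self, variables: list[str] | None = None) -> np.ndarray:
        """Stack layers into an (n_pixels, n_vars) matrix (row-major pixels)."""
        variables = variables or self.variables
        return np.column_stack([self.layers[v].ravel() for v in variables])

    def save(self, directory: str | Path, ext: str = ".asc") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, data in self.layers.items():
            write_raster(directory / f"{name.lower()}{ext}", data, self.grid)


def derive_bioclim(stack: MonthlyClimateStack, window: MonthWindow) -> BioclimSet:
    """Derive the window-specific bioclim variable set from a monthly stack.

    All statistics are symmetric in the window months.  Nodata (NaN in any
    contributing monthly layer) propagates to every derived layer.  A window
    of length 1 is rejected because the seasonality SDs are undefined.
    Pixels with zero window temperature range get BIO3 = NaN with a warning.
    """
    if len(window) < 2:
        raise ValueError(
            "bioclim derivation needs a window of at least 2 months "
            "(seasonality SDs are undefined for a single month)"
        )
    # canonical month order: every statistic is symmetric in the months,
    # so sorting makes the float summation order (and hence the result)
    # independent of how the window was written
    idx = np.sort(window.indices)
    tmin = stack.tmin[idx]
    tmax = stack.tmax[idx]
    prec = stack.prec[idx]
    tavg = (tmin + tmax) / 2.0

    with warnings.catch_warnings():
        # all-NaN pixels raise RuntimeWarnings we deliberately propagate as NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        bio1 = np.mean(tavg, axis=0)
        bio2 = np.mean(tmax - tmin, axis=0)
        trange = np.max(tmax, axis=0) - np.min(tmin, axis=0)
        bio4 = 100.0 * np.std(tavg, axis=0, ddof=1)
        bio6 = np.min(tmin, axis=0)
        prec_mean = np.mean(prec, axis=0)
        bio15 = 100.0 * np.std(prec, axis=0, ddof=1) / (1.0 + prec_mean)
        min_tmax = np.min(tmax, axis=0)
        mean_tmin = np.mean(tmin, axis=0)

        zero_range = (trange == 0) & ~np.isnan(trange)
        if np.any(zero_range):
            warnings.warn(
                f"{int(zero_range.sum())} pixel(s) have zero temperature range "
                "over the window; BIO3 set to nodata there",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            bio3 = 100.0 * bio2 / trange
        bio3 = np.where(zero_range, np.nan, bio3)

    layers = {
        "BIO1": bio1,
        "BIO2": bio2,
        "BIO3": bio3,
        "BIO4": bio4,
        "BIO6": bio6,
        "BIO15": bio15,
        "minTmax": min_tmax,
        "meanTmin": mean_tmin,
    }
    # propagate nodata from any monthly input
    invalid = ~stack.valid_mask()
    for name in layers:
        layers[name] = np.where(invalid, np.nan, layers[name])
    return BioclimSet(grid=stack.grid, window=window, layers=layers)


def extract_at_points(
    bioclim: BioclimSet,
    lon,
    lat,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Sample derived variables at lon/lat points (one row per point).

    Columns follow the configured variable order; a boolean ``valid`` column
    flags rows free of nodata.  Points outside the raster extent raise.
    """
    variables = variables or bioclim.variables
    row, col = bioclim.grid.point_to_rowcol(lon, lat)
    data = {v: bioclim.layers[v][row, col] for v in variables}
    df = pd.DataFrame(data)
    df["valid"] = ~df[variables].isna().any(axis=1)
    return df
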