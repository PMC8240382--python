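"""Synthetic climate worlds with clade-structured occurrences.

Stand-in for the real monthly climate product and the published occurrence
coordinates: smooth Gaussian-random-field climate surfaces with an annual
temperature cycle, plus six clades (two oviparous, four viviparous) whose
occurrences are drawn with Gaussian suitability around clade-specific
niche centroids in chosen bioclim variables.  Every pipeline stage can be
exercised on these worlds without any download, and presets encode the
qualitative scenarios of interest (no niche difference; viviparous clades
in less seasonally variable reproductive climates; colder viviparous
climates; more variable viviparous climates; and a reproductive-vs-annual
sign reversal in temperature seasonality).

Per-pixel monthly mean temperature is

    T(m) = base + a1 * cos(2*pi*(m-7)/12) + a2 * cos(4*pi*(m-7)/12) + noise_m

with ``base``, the harmonic amplitudes ``a1``/``a2`` and the diurnal range
low-frequency random fields; tmin/tmax sit half a diurnal range below/above
T(m).  The second harmonic decouples reproductive-window (May-July)
seasonality from annual seasonality, which is what makes the sign-reversal
scenario geographically realizable.  Monthly precipitation is log-normal
with a seasonally modulated exponent, so precipitation seasonality (BIO15)
also varies in space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .bioclim import BioclimSet, derive_bioclim
from .grid import ANNUAL, REPRODUCTIVE, GeoGrid, MonthlyClimateStack, window_by_name
from .occurrences import CLADES, PARITY_OF_CLADE, validate_occurrences

__all__ = [
    "SyntheticScenario",
    "generate_monthly_stack",
    "generate_occurrences",
    "generate_dataset",
    "preset",
    "PRESETS",
]

_MONTHS = np.arange(1, 13)
_C1 = np.cos(2 * np.pi * (_MONTHS - 7) / 12.0)
_C2 = np.cos(4 * np.pi * (_MONTHS - 7) / 12.0)

#: per-clade occurrence counts mirroring the real 185-population sample
DEFAULT_N_PER_CLADE = {"A": 37, "B": 41, "C": 19, "D": 26, "E": 47, "F": 15}


@dataclass
class SyntheticScenario:
    """All knobs of one synthetic world; reproducible given (scenario, seed)."""

    name: str = "custom"
    n_rows: int = 200
    n_cols: int = 200
    origin_lon: float = -10.0
    origin_lat: float = 60.0
    pixel_size: float = 0.05
    n_per_clade: dict = field(default_factory=lambda: dict(DEFAULT_N_PER_CLADE))
    #: clade -> {(window_name, variable): centroid offset in field-SD units}
    niche_offsets: dict = field(default_factory=dict)
    #: suitability kernel width in field-SD units
    suitability_width: float = 0.5
    #: correlation length of the random fields, in pixels
    smoothness: float = 15.0
    base_mean: float = 9.0
    base_sd: float = 6.0
    amp1_mean: float = 8.0
    amp1_sd: float = 2.5
    amp2_mean: float = 0.0
    amp2_sd: float = 2.0
    diurnal_mean: float = 8.0
    diurnal_sd: float = 2.0
    month_noise_sd: float = 0.3
    log_prec_mean: float = 4.1  # ~ 60 mm/month
    log_prec_sd: float = 0.4
    prec_season_mean: float = 0.4
    prec_season_sd: float = 0.3
    seed: int = 0

    @property
    def grid(self) -> GeoGrid:
        return GeoGrid(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            pixel_size=self.pixel_size,
        )

    def windows_needed(self) -> list[str]:
        names = {w for offs in self.niche_offsets.values() for (w, _) in offs}
        return sorted(names) or ["reproductive"]


def _grf(shape, sigma, mean, sd, rng) -> np.ndarray:
    """Gaussian random field: smoothed white noise re-standardized so the
    marginal distribution is N(mean, sd) regardless of sigma."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    s = f.std()
    if s > 0:
        f = (f - f.mean()) / s
    return mean + sd * f


def generate_monthly_stack(
    scenario: SyntheticScenario, seed: int | None = None
) -> MonthlyClimateStack:
    """Generate the 36 monthly layers (tmin/tmax/prec) of one world."""
    sc = scenario
    rng = np.random.default_rng(sc.seed if seed is None else seed)
    shape = (sc.n_rows, sc.n_cols)
    sig = sc.smoothness
    base = _grf(shape, sig, sc.base_mean, sc.base_sd, rng)
    a1 = _grf(shape, sig, sc.amp1_mean, sc.amp1_sd, rng)
    a2 = _grf(shape, sig, sc.amp2_mean, sc.amp2_sd, rng)
    dr = np.clip(_grf(shape, sig, sc.diurnal_mean, sc.diurnal_sd, rng), 0.5, None)
    logp = _grf(shape, sig, sc.log_prec_mean, sc.log_prec_sd, rng)
    w = _grf(shape, sig, sc.prec_season_mean, sc.prec_season_sd, rng)

    tavg = base[None] + a1[None] * _C1[:, None, None] + a2[None] * _C2[:, None, None]
    if sc.month_noise_sd > 0:
        noise = np.stack(
            [_grf(shape, sig / 2, 0.0, sc.month_noise_sd, rng) for _ in range(12)]
        )
        tavg = tavg + noise
    tmin = tavg - dr[None] / 2.0
    tmax = tavg + dr[None] / 2.0
    prec = np.exp(logp[None] + w[None] * _C1[:, None, None])
    return MonthlyClimateStack(grid=sc.grid, tmin=tmin, tmax=tmax, prec=prec)


def generate_occurrences(
    scenario: SyntheticScenario,
    bioclim: dict[str, BioclimSet],
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample clade occurrences with Gaussian suitability around each
    clade's niche centroid.

    ``bioclim`` maps window names to derived variable sets of the same
    world.  Centroid offsets are in units of the field's spatial SD, so a
    -1.5 offset puts a clade 1.5 SD below the landscape mean of that
    variable.  Clades without offsets sample around the landscape mean.
    Raises when a requested centroid is effectively unreachable.
    """
    sc = scenario
    rng = np.random.default_rng((sc.seed if seed is None else seed) + 1)
    any_set = next(iter(bioclim.values()))
    grid = any_set.grid
    valid = ~np.isnan(any_set.matrix()).any(axis=1)
    for bs in bioclim.values():
        valid &= ~np.isnan(bs.matrix()).any(axis=1)

    # standardized landscape layers, keyed by (window, variable)
    std_layers: dict[tuple[str, str], np.ndarray] = {}
    keys = {k for offs in sc.niche_offsets.values() for k in offs}
    for win, var in keys:
        v = bioclim[win][var].ravel()
        mu, sd = np.nanmean(v), np.nanstd(v)
        if sd == 0:
            raise ValueError(f"variable {var} ({win}) has no spatial variation")
        std_layers[(win, var)] = (v - mu) / sd

    rows = []
    n_cols = grid.n_cols
    for clade in CLADES:
        n = sc.n_per_clade.get(clade, 0)
        if n == 0:
            continue
        log_suit = np.zeros(valid.sum())
        for key, offset in sc.niche_offsets.get(clade, {}).items():
            z = std_layers[key][valid]
            log_suit -= (z - offset) ** 2 / (2.0 * sc.suitability_width**2)
        suit = np.exp(log_suit - log_suit.max())
        total = suit.sum()
        if not np.isfinite(total) or total < n:
            raise ValueError(
                f"clade {clade}: suitability mass too small - the requested "
                "niche centroid is unreachable in this world; relax the "
                "offsets or widen suitability_width"
            )
        p = suit / total
        chosen = rng.choice(np.flatnonzero(valid), size=n, replace=False, p=p)
        lon, lat = grid.rowcol_to_center(chosen // n_cols, chosen % n_cols)
        for x, y in zip(lon, lat):
            rows.append(
                {"lon": x, "lat": y, "clade": clade, "parity": PARITY_OF_CLADE[clade]}
            )
    return validate_occurrences(pd.DataFrame(rows))


def generate_dataset(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[MonthlyClimateStack, dict[str, BioclimSet], pd.DataFrame]:
    """World + derived bioclim (for the scenario's windows) + occurrences."""
    stack = generate_monthly_stack(scenario, seed=seed)
    bioclim = {
        name: derive_bioclim(stack, window_by_name(name))
        for name in set(scenario.windows_needed()) | {"reproductive", "annual"}
    }
    occ = generate_occurrences(scenario, bioclim, seed=seed)
    return stack, bioclim, occ


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_OVI = ("A", "B")
_VIVI = ("C", "D", "E", "F")


def _split_offsets(keys: list[tuple[str, str]], ovi: float, vivi: float) -> dict:
    offs = {}
    for c in _OVI:
        offs[c] = {k: ovi for k in keys}
    for c in _VIVI:
        offs[c] = {k: vivi for k in keys}
    return offs


def _anchor(offs: dict, keys: list[tuple[str, str]]) -> dict:
    """Pin extra variables to the landscape mean for every clade.

    The seasonal amplitude also shifts the window's *average* temperatures
    (the annual cosine does not average to zero over May-July, and its
    window minimum differs from its window mean), so a variability-only
    scenario must hold every average-temperature centroid fixed explicitly
    - otherwise selecting for low seasonality would, as a side effect,
    select sites with different average climates and contaminate the
    scenario.
    """
    for clade in offs:
        for k in keys:
            offs[clade].setdefault(k, 0.0)
    return offs


_AVG_ANCHORS = [
    ("reproductive", "meanTmin"),
    ("reproductive", "minTmax"),
    ("reproductive", "BIO6"),
]


def _null() -> dict:
    keys = [("reproductive", "BIO4"), ("reproductive", "BIO15")]
    return _split_offsets(keys, 0.0, 0.0)


def _smh_reproductive() -> dict:
    # viviparous clades 1.5 field-SD below oviparous in reproductive-window
    # temperature and precipitation seasonality; average temperature equal
    keys = [("reproductive", "BIO4"), ("reproductive", "BIO15")]
    return _anchor(_split_offsets(keys, +0.75, -0.75), _AVG_ANCHORS)


def _cch_cold() -> dict:
    # colder viviparous sites with equal seasonality
    keys = [("reproductive", "meanTmin"), ("reproductive", "BIO6")]
    return _anchor(_split_offsets(keys, +0.75, -0.75),
                   [("reproductive", "BIO4"), ("reproductive", "BIO15")])


def _mmh_variable() -> dict:
    keys = [("reproductive", "BIO4"), ("reproductive", "BIO15")]
    return _anchor(_split_offsets(keys, -0.75, +0.75), _AVG_ANCHORS)


def _annual_reversal() -> dict:
    offs = {}
    for c in _OVI:
        offs[c] = {("reproductive", "BIO4"): +0.75, ("annual", "BIO4"): -0.75}
    for c in _VIVI:
        offs[c] = {("reproductive", "BIO4"): -0.75, ("annual", "BIO4"): +0.75}
    return offs


PRESETS = {
    "null": _null,
    "smh_reproductive": _smh_reproductive,
    "cch_cold": _cch_cold,
    "mmh_variable": _mmh_variable,
    "annual_reversal": _annual_reversal,
}


def preset(name: str, seed: int = 0, **overrides) -> SyntheticScenario:
    """Named scenario; unknown names raise with the list of presets."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    sc = SyntheticScenario(name=name, niche_offsets=PRESETS[name](), seed=seed)
    return replace(sc, **overrides) if overrides else sc
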