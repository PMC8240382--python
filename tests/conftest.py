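import numpy as np
import pandas as pd
import pytest

from parityniche import (
    GeoGrid,
    MonthlyClimateStack,
    generate_dataset,
    preset,
)


def make_stack(tmin, tmax, prec, pixel_size=1.0):
    """Stack from (12, r, c) arrays with a simple unit grid."""
    tmin = np.asarray(tmin, dtype=float)
    grid = GeoGrid(
        n_rows=tmin.shape[1],
        n_cols=tmin.shape[2],
        origin_lon=0.0,
        origin_lat=float(tmin.shape[1] * pixel_size),
        pixel_size=pixel_size,
    )
    return MonthlyClimateStack(
        grid=grid,
        tmin=tmin,
        tmax=np.asarray(tmax, dtype=float),
        prec=np.asarray(prec, dtype=float),
    )


def constant_monthly_stack(tavg_by_month, diurnal=4.0, prec_by_month=None, shape=(3, 4)):
    """Spatially constant stack with prescribed monthly means."""
    r, c = shape
    tavg = np.asarray(tavg_by_month, dtype=float)[:, None, None] * np.ones((12, r, c))
    prec = (
        np.asarray(prec_by_month, dtype=float)[:, None, None] * np.ones((12, r, c))
        if prec_by_month is not None
        else np.full((12, r, c), 50.0)
    )
    return make_stack(tavg - diurnal / 2, tavg + diurnal / 2, prec)


@pytest.fixture(scope="session")
def smh_world():
    """One SMH-scenario synthetic world shared across tests (read-only)."""
    scenario = preset("smh_reproductive", seed=7)
    stack, bioclim, occ = generate_dataset(scenario)
    return scenario, stack, bioclim, occ


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_classification_data(seed, n=60, p=3, shift=1.5):
    """Two-class covariate fixture with a shifted first variable."""
    rng = np.random.default_rng(seed)
    y = np.repeat(["a", "b"], n // 2)
    X = rng.normal(size=(n, p))
    X[y == "b", 0] += shift
    return X, y
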