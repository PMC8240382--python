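"""Raster grid primitives and monthly climate stacks.

Everything downstream (bioclim derivation, niche ordination, the synthetic
world) shares one raster convention: geographic lon/lat, pixel-is-area,
0-based row/col with row 0 at the *top* (highest latitude), and point-to-pixel
lookup by ``floor((coord - origin) / pixel_size)``.

On-disk formats are single-band ESRI ASCII grids (``.asc``, plain text) or
single-band TIFF (``.tif``) written with :mod:`tifffile`; for TIFF the grid
geometry travels in the ImageDescription tag as JSON.  Monthly stacks live in
a directory of 36 rasters named ``tmin_01`` ... ``prec_12``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeoGrid",
    "MonthWindow",
    "ANNUAL",
    "REPRODUCTIVE",
    "MonthlyClimateStack",
    "read_raster",
    "write_raster",
]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GeoGrid:
    """Geometry shared by all index-aligned raster layers of one analysis.

    ``origin_lon``/``origin_lat`` locate the upper-left corner of the
    upper-left pixel (not its center); ``pixel_size`` is in decimal degrees.
    """

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    pixel_size: float
    crs_tag: str = "EPSG:4326"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.pixel_size

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.pixel_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) at pixel centers."""
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    def point_to_rowcol(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map lon/lat (scalars or arrays) to 0-based (row, col) indices.

        Points outside the raster extent raise ``ValueError`` naming the
        first offending point.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        col = np.floor((lon - self.origin_lon) / self.pixel_size).astype(int)
        row = np.floor((self.origin_lat - lat) / self.pixel_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"point (lon={lon[i]:.6g}, lat={lat[i]:.6g}) falls outside the "
                f"raster extent"
            )
        return row, col

    def rowcol_to_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        lon = self.origin_lon + (np.asarray(col) + 0.5) * self.pixel_size
        lat = self.origin_lat - (np.asarray(row) + 0.5) * self.pixel_size
        return lon, lat

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "origin_lon": self.origin_lon,
            "origin_lat": self.origin_lat,
            "pixel_size": self.pixel_size,
            "crs_tag": self.crs_tag,
            "nodata": self.nodata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeoGrid":
        return cls(**d)


# ---------------------------------------------------------------------------
# month windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonthWindow:
    """An ordered set of calendar months (1-12) over which bioclim
    statistics are taken.

    The two study windows are :data:`ANNUAL` (all twelve months) and
    :data:`REPRODUCTIVE` (May-July, the egg-laying/gestation season of the
    common lizard).
    """

    months: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.months) == 0:
            raise ValueError("month window must be non-empty")
        if len(set(self.months)) != len(self.months):
            raise ValueError("month window has duplicate months")
        if any(m < 1 or m > 12 for m in self.months):
            raise ValueError("months must be in 1..12")

    def __len__(self) -> int:
        return len(self.months)

    @property
    def indices(self) -> np.ndarray:
        """0-based indices into a 12-layer monthly array."""
        return np.asarray(self.months, dtype=int) - 1


ANNUAL = MonthWindow(tuple(range(1, 13)), name="annual")
REPRODUCTIVE = MonthWindow((5, 6, 7), name="reproductive")

_WINDOWS = {"annual": ANNUAL, "reproductive": REPRODUCTIVE}


def window_by_name(name: str) -> MonthWindow:
    try:
        return _WINDOWS[name]
    except KeyError:
        raise ValueError(
            f"unknown window {name!r}; known presets: {sorted(_WINDOWS)}"
        ) from None


# ---------------------------------------------------------------------------
# single-band raster I/O
# ---------------------------------------------------------------------------


def write_raster(path: str | Path, data: np.ndarray, grid: GeoGrid) -> None:
    """Write one raster layer; format chosen by extension (.asc or .tif)."""
    path = Path(path)
    data = np.asarray(data, dtype=float)
    if data.shape != grid.shape:
        raise ValueError(f"data shape {data.shape} != grid shape {grid.shape}")
    if path.suffix == ".asc":
        _write_ascii(path, data, grid)
    elif path.suffix in (".tif", ".tiff"):
        _write_tiff(path, data, grid)
    else:
        raise ValueError(f"unsupported raster extension {path.suffix!r}")


def read_raster(path: str | Path) -> tuple[np.ndarray, GeoGrid]:
    path = Path(path)
    if path.suffix == ".asc":
        return _read_ascii(path)
    if path.suffix in (".tif", ".tiff"):
        return _read_tiff(path)
    raise ValueError(f"unsupported raster extension {path.suffix!r}")


def _write_ascii(path: Path, data: np.ndarray, grid: GeoGrid) -> None:
    out = np.where(np.isnan(data), grid.nodata, data)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon!r}\n"
        f"yllcorner {grid.origin_lat - grid.n_rows * grid.pixel_size!r}\n"
        f"cellsize {grid.pixel_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def _read_ascii(path: Path) -> tuple[np.ndarray, GeoGrid]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    grid = GeoGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * header["cellsize"],
        pixel_size=header["cellsize"],
        nodata=nodata,
    )
    data = np.atleast_2d(np.asarray(data, dtype=float))
    data = np.where(data == nodata, np.nan, data)
    return data, grid


def _write_tiff(path: Path, data: np.ndarray, grid: GeoGrid) -> None:
    import tifffile

    out = np.where(np.isnan(data), grid.nodata, data).astype(np.float32)
    tifffile.imwrite(path, out, description=json.dumps(grid.to_dict()))


def _read_tiff(path: Path) -> tuple[np.ndarray, GeoGrid]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        if desc is None:
            raise ValueError(f"{path}: TIFF lacks the grid-geometry description tag")
        grid = GeoGrid.from_dict(json.loads(desc.value))
    data = np.where(data == grid.nodata, np.nan, data)
    return data, grid


# ---------------------------------------------------------------------------
# monthly stacks
# ---------------------------------------------------------------------------

_STACK_VARS = ("tmin", "tmax", "prec")


@dataclass
class MonthlyClimateStack:
    """Twelve monthly layers each of tmin/tmax (degC) and prec (mm).

    Arrays have shape (12, n_rows, n_cols); nodata is NaN in memory.
    An optional integer-storage ``scale`` (the classic x10 dialect of
    global climate products) can be applied at read time.
    """

    grid: GeoGrid
    tmin: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray

    def __post_init__(self) -> None:
        for name in _STACK_VARS:
            arr = getattr(self, name)
            if arr.shape != (12, *self.grid.shape):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {(12, *self.grid.shape)}"
                )
        self.validate()

    def validate(self) -> None:
        valid = self.valid_mask()
        if np.any(self.tmax[:, valid] < self.tmin[:, valid]):
            raise ValueError("tmax < tmin at some valid pixel/month")
        if np.any(self.prec[:, valid] < 0):
            raise ValueError("negative precipitation at some valid pixel/month")

    def valid_mask(self) -> np.ndarray:
        """Pixels with all 36 monthly values present."""
        ok = np.ones(self.grid.shape, dtype=bool)
        for name in _STACK_VARS:
            ok &= ~np.any(np.isnan(getattr(self, name)), axis=0)
        return ok

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path, ext: str = ".asc") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in _STACK_VARS:
            arr = getattr(self, name)
            for m in range(12):
                write_raster(directory / f"{name}_{m + 1:02d}{ext}", arr[m], self.grid)

    @classmethod
    def load(
        cls,
        directory: str | Path,
        ext: str = ".asc",
        temperature_scale: float = 1.0,
    ) -> "MonthlyClimateStack":
        """Read ``tmin_01`` ... ``prec_12`` from *directory*.

        ``temperature_scale`` divides tmin/tmax after reading (pass 10 for
        integer-storage x10 products).
        """
        directory = Path(directory)
        layers: dict[str, list[np.ndarray]] = {v: [] for v in _STACK_VARS}
        grid: GeoGrid | None = None
        for name in _STACK_VARS:
            for m in range(1, 13):
                p = directory / f"{name}_{m:02d}{ext}"
                if not p.exists():
                    raise FileNotFoundError(f"missing monthly raster {p}")
                data, g = read_raster(p)
                if grid is None:
                    grid = g
                elif g.shape != grid.shape or g.pixel_size != grid.pixel_size:
                    raise ValueError(f"{p}: grid geometry differs from first layer")
                layers[name].append(data)
        assert grid is not None
        tmin = np.stack(layers["tmin"]) / temperature_scale
        tmax = np.stack(layers["tmax"]) / temperature_scale
        return cls(grid=grid, tmin=tmin, tmax=tmax, prec=np.stack(layers["prec"]))
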