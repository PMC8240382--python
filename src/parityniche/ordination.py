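"""PCA-env niche ordination, kernel occupancy surfaces and Schoener's D.

The ordination follows the environmental-PCA niche framework: a
correlation-matrix PCA is calibrated on background pixels (drawn inside the
convex hull of all occurrences) pooled with the occurrence pixels; a
100 x 100 grid is laid over the first two axes; each clade's occurrence
kernel density is corrected by the background (availability) density and
normalized into an occupancy surface z with sum 1; niche overlap between two
clades is Schoener's D = 1 - 0.5 * sum |z1 - z2|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .grid import GeoGrid

__all__ = [
    "convex_hull_mask",
    "sample_background",
    "BackgroundSample",
    "OrdinationModel",
    "fit_pca_env",
    "project",
    "SurfaceGrid",
    "NicheSurface",
    "silverman_bandwidth",
    "occupancy_surface",
    "schoener_d",
    "clade_centroid",
]


# ---------------------------------------------------------------------------
# study extent: convex hull of the occurrences
# ---------------------------------------------------------------------------


def convex_hull_mask(lon, lat, grid: GeoGrid) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside (or on) the convex
    hull of the occurrence points.

    The hull is the study extent: within it the species can be assumed to
    have encountered the available climates, which keeps uninformative
    absences out of the background sample.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size < 3:
        raise ValueError("convex hull needs at least 3 occurrence points")
    hull = shapely.MultiPoint(np.column_stack([lon, lat])).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("occurrence points are collinear; hull is degenerate")
    glon, glat = grid.center_mesh()
    shapely.prepare(hull)
    # intersects (not contains) so that boundary pixel centers count as inside
    mask = shapely.intersects_xy(hull, glon.ravel(), glat.ravel())
    return mask.reshape(grid.shape)


@dataclass
class BackgroundSample:
    """Random background pixels (availability sample) inside the hull mask."""

    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray  # (n, n_vars) bioclim rows
    variables: list[str]
    rng_seed: int

    @property
    def n(self) -> int:
        return len(self.rows)


def sample_background(
    mask: np.ndarray,
    bioclim_matrix: np.ndarray,
    variables: list[str],
    n: int,
    seed: int,
) -> BackgroundSample:
    """Sample *n* distinct masked pixels uniformly; rows with nodata in any
    variable are excluded from the candidate pool before sampling.
    """
    flat_ok = mask.ravel() & ~np.isnan(bioclim_matrix).any(axis=1)
    candidates = np.flatnonzero(flat_ok)
    if n > candidates.size:
        raise ValueError(
            f"requested {n} background pixels but only {candidates.size} valid "
            f"pixels lie inside the hull"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n, replace=False)
    n_cols = mask.shape[1]
    return BackgroundSample(
        rows=chosen // n_cols,
        cols=chosen % n_cols,
        values=bioclim_matrix[chosen],
        variables=list(variables),
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# correlation-matrix PCA
# ---------------------------------------------------------------------------


@dataclass
class OrdinationModel:
    """Correlation-matrix PCA calibrated on background + occurrence rows.

    ``loadings[:, k]`` is the k-th axis; standardization uses the
    calibration mean and sample SD (ddof=1).  Axis signs are fixed so each
    axis's largest-magnitude loading is positive.
    """

    variables: list[str]
    mean: np.ndarray
    sd: np.ndarray
    loadings: np.ndarray  # (n_vars, n_vars), columns = axes
    explained: np.ndarray  # fractions, sum to 1

    @property
    def n_vars(self) -> int:
        return len(self.variables)


def fit_pca_env(
    background_rows: np.ndarray,
    occurrence_rows: np.ndarray,
    variables: list[str],
) -> OrdinationModel:
    """Fit the PCA on the pooled calibration set (background + occurrences)."""
    X = np.vstack([background_rows, occurrence_rows]).astype(float)
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    if np.isnan(X).any():
        raise ValueError("calibration rows contain nodata; filter before fitting")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if np.any(zero):
        names = [v for v, z in zip(variables, zero) if z]
        raise ValueError(f"zero-variance variable(s): {names}")
    Z = (X - mean) / sd
    corr = (Z.T @ Z) / (len(Z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # reproducible sign convention
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    return OrdinationModel(
        variables=list(variables),
        mean=mean,
        sd=sd,
        loadings=eigvec,
        explained=eigval / eigval.sum(),
    )


def project(model: OrdinationModel, rows: np.ndarray, n_axes: int = 2) -> np.ndarray:
    """Project variable rows into the calibrated PC space (first n_axes)."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim == 1:
        rows = rows[None, :]
    if rows.shape[1] != model.n_vars:
        raise ValueError(
            f"rows have {rows.shape[1]} variables, model expects {model.n_vars}"
        )
    Z = (rows - model.mean) / model.sd
    return Z @ model.loadings[:, :n_axes]


# ---------------------------------------------------------------------------
# kernel occupancy surfaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceGrid:
    """Shared extents and resolution of the ordination-space grid.

    Extents come from the pooled background scores expanded by a margin so
    kernels are not clipped; every clade of one run must share the same
    SurfaceGrid for the overlaps to be comparable.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    size: int = 100

    @classmethod
    def from_scores(cls, scores: np.ndarray, size: int = 100, margin: float = 0.05):
        x_min, y_min = scores.min(axis=0)[:2]
        x_max, y_max = scores.max(axis=0)[:2]
        dx = (x_max - x_min) * margin
        dy = (y_max - y_min) * margin
        return cls(x_min - dx, x_max + dx, y_min - dy, y_max + dy, size)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        sx = (self.x_max - self.x_min) / self.size
        sy = (self.y_max - self.y_min) / self.size
        x = self.x_min + (np.arange(self.size) + 0.5) * sx
        y = self.y_min + (np.arange(self.size) + 0.5) * sy
        return x, y


@dataclass
class NicheSurface:
    """Availability-corrected occupancy of one clade on the shared grid.

    ``o`` and ``e`` are the occurrence and background kernel densities, each
    normalized to sum 1; ``z`` is the occupancy surface (o/e where the
    background supports the cell, in corrected mode), normalized to sum 1.
    """

    grid: SurfaceGrid
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray
    clade: str = ""
    bandwidths: tuple[float, float] = (np.nan, np.nan)
    mode: str = "corrected"


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb for a 1-D Gaussian kernel."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        return 1.0
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25])) * -1
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        spread = max(abs(values[0]), 1.0) * 1e-3
    return 0.9 * spread * n ** (-0.2)


def _grid_density(
    points: np.ndarray, grid: SurfaceGrid, hx: float, hy: float
) -> np.ndarray:
    """Gaussian product-kernel density at cell centers, normalized to sum 1.

    Separable kernel: density = A @ B.T with A, B the per-axis kernel
    matrices, which keeps the 100x100 evaluation cheap inside permutation
    loops.  Rows index the x axis, columns the y axis.
    """
    gx, gy = grid.centers()
    x = points[:, 0]
    y = points[:, 1]
    A = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2)
    B = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2)
    dens = A @ B.T
    total = dens.sum()
    if total <= 0:
        raise ValueError("kernel density vanished on the grid (points outside extents?)")
    return dens / total


def occupancy_surface(
    occ_scores: np.ndarray,
    bg_scores: np.ndarray,
    grid: SurfaceGrid | None = None,
    mode: str = "corrected",
    bandwidth_scale: float = 1.0,
    clade: str = "",
    _bg_density: np.ndarray | None = None,
) -> NicheSurface:
    """Build a clade's occupancy surface on the shared ordination grid.

    mode "corrected" divides occurrence density by background availability
    (cells with essentially zero availability get z = 0); mode "raw" uses
    the occurrence density alone.  ``_bg_density`` lets permutation loops
    reuse the availability surface, which does not change between replicates.
    """
    occ_scores = np.atleast_2d(np.asarray(occ_scores, dtype=float))
    if occ_scores.shape[0] == 0:
        raise ValueError("empty occurrence score set")
    if mode not in ("corrected", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    if grid is None:
        grid = SurfaceGrid.from_scores(bg_scores)

    hx = silverman_bandwidth(occ_scores[:, 0]) * bandwidth_scale
    hy = silverman_bandwidth(occ_scores[:, 1]) * bandwidth_scale
    o = _grid_density(occ_scores, grid, hx, hy)

    if _bg_density is not None:
        e = _bg_density
    else:
        ex = silverman_bandwidth(bg_scores[:, 0]) * bandwidth_scale
        ey = silverman_bandwidth(bg_scores[:, 1]) * bandwidth_scale
        e = _grid_density(np.asarray(bg_scores, dtype=float), grid, ex, ey)

    if mode == "corrected":
        eps = 1e-12 * e.max()
        if not np.any(e > eps):
            raise ValueError("background density is zero everywhere on the grid")
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(e > eps, o / e, 0.0)
    else:
        z = o.copy()
    z_sum = z.sum()
    if z_sum <= 0:
        raise ValueError("occupancy surface has no mass inside the supported extent")
    return NicheSurface(
        grid=grid, o=o, e=e, z=z / z_sum, clade=clade, bandwidths=(hx, hy), mode=mode
    )


def schoener_d(z1, z2) -> float:
    """Schoener's D = 1 - 0.5 * sum |z1 - z2| between two occupancy surfaces.

    Accepts NicheSurface objects or bare normalized grids; surfaces must
    share the grid geometry.  D is 1 for identical surfaces and 0 for
    disjoint supports.
    """
    if isinstance(z1, NicheSurface) and isinstance(z2, NicheSurface):
        if z1.grid != z2.grid:
            raise ValueError("surfaces live on different ordination grids")
        a, b = z1.z, z2.z
    else:
        a = np.asarray(z1, dtype=float)
        b = np.asarray(z2, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    d = 1.0 - 0.5 * np.abs(a - b).sum()
    return float(min(max(d, 0.0), 1.0))


def clade_centroid(scores: np.ndarray) -> tuple[float, float]:
    """Mean position of a clade's occurrences on the first two axes."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 0:
        raise ValueError("no scores")
    m = scores[:, :2].mean(axis=0)
    return float(m[0]), float(m[1])
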