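"""Permutation tests of niche similarity and equivalency.

Both tests compare the observed Schoener's D of a clade pair with a null
distribution of 1000 (configurable) simulated overlaps:

* similarity: each clade's occupancy surface is translated by a random
  cell offset within the background-supported extent (two-tailed);
* equivalency: the pooled occurrences of the pair are randomly re-assigned
  to the two clades, the surfaces are rebuilt from scratch, and the test is
  lower-tailed (rejects when the clades' niches overlap less than random
  re-labelling would allow).

p-values use the add-one convention (the observed value counts as one more
member of the null), so the smallest attainable p is 1/(n_reps + 1) and p
is never 0.  Replicate r draws its randomness from seed ``base_seed + r``,
which makes the null distribution independent of any parallel scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ordination import NicheSurface, SurfaceGrid, occupancy_surface, schoener_d

__all__ = [
    "OverlapTestResult",
    "compare_to_null",
    "similarity_test",
    "equivalency_test",
    "significance_code",
]


@dataclass
class OverlapTestResult:
    clade_pair: tuple[str, str]
    d_obs: float
    d_sim: np.ndarray
    tail: str  # "two_tailed_similarity" | "lower_tailed_equivalency"
    p_value: float
    rng_seed: int

    @property
    def n_reps(self) -> int:
        return len(self.d_sim)

    def to_dict(self) -> dict:
        return {
            "clade_pair": list(self.clade_pair),
            "d_obs": self.d_obs,
            "tail": self.tail,
            "p_value": self.p_value,
            "n_reps": self.n_reps,
            "rng_seed": self.rng_seed,
            "d_sim": [float(v) for v in self.d_sim],
        }


def compare_to_null(d_obs: float, d_sim: np.ndarray, tail: str) -> float:
    """Permutation p-value with the add-one convention.

    tail "lower": p = (1 + #{d_sim <= d_obs}) / (n + 1);
    tail "upper": analogous with >=;
    tail "two": min(1, 2 * min(p_lower, p_upper)).
    """
    d_sim = np.asarray(d_sim, dtype=float)
    if d_sim.size == 0:
        raise ValueError("empty null distribution")
    n = d_sim.size
    p_lo = (1 + np.sum(d_sim <= d_obs)) / (n + 1)
    p_hi = (1 + np.sum(d_sim >= d_obs)) / (n + 1)
    if tail == "lower":
        return float(p_lo)
    if tail == "upper":
        return float(p_hi)
    if tail == "two":
        return float(min(1.0, 2.0 * min(p_lo, p_hi)))
    raise ValueError(f"unknown tail {tail!r}")


def _shift_surface(
    z: np.ndarray, support: np.ndarray, rng: np.random.Generator, max_tries: int = 1000
) -> np.ndarray:
    """Translate z by a uniform random cell offset; cells shifted outside
    the grid or off the background-supported cells are dropped and the
    remainder renormalized.  Offsets leaving no mass are rejected and
    redrawn.
    """
    n_r, n_c = z.shape
    for _ in range(max_tries):
        di = int(rng.integers(-(n_r - 1), n_r))
        dj = int(rng.integers(-(n_c - 1), n_c))
        shifted = np.zeros_like(z)
        src_r = slice(max(0, -di), min(n_r, n_r - di))
        src_c = slice(max(0, -dj), min(n_c, n_c - dj))
        dst_r = slice(max(0, di), min(n_r, n_r + di))
        dst_c = slice(max(0, dj), min(n_c, n_c + dj))
        shifted[dst_r, dst_c] = z[src_r, src_c]
        shifted[~support] = 0.0
        total = shifted.sum()
        if total > 0:
            return shifted / total
    raise RuntimeError("could not draw a mass-preserving shift (support too small?)")


def similarity_test(
    surf_a: NicheSurface,
    surf_b: NicheSurface,
    n_reps: int = 1000,
    seed: int = 0,
    shift_both: bool = True,
) -> OverlapTestResult:
    """Niche similarity test: random translation of the occupancy surfaces.

    By default both clades' surfaces are shifted independently each
    replicate; ``shift_both=False`` shifts only the second surface (the
    one-sided-shift variant).  Two-tailed p.
    """
    if surf_a.grid != surf_b.grid:
        raise ValueError("surfaces live on different ordination grids")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    support = surf_a.e > 1e-12 * surf_a.e.max()
    if not support.any():
        raise ValueError("background support is empty")
    d_obs = schoener_d(surf_a, surf_b)
    d_sim = np.empty(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        za = _shift_surface(surf_a.z, support, rng) if shift_both else surf_a.z
        zb = _shift_surface(surf_b.z, support, rng)
        d_sim[r] = schoener_d(za, zb)
    p = compare_to_null(d_obs, d_sim, "two")
    return OverlapTestResult(
        clade_pair=(surf_a.clade, surf_b.clade),
        d_obs=d_obs,
        d_sim=d_sim,
        tail="two_tailed_similarity",
        p_value=p,
        rng_seed=seed,
    )


def equivalency_test(
    occ_a: np.ndarray,
    occ_b: np.ndarray,
    bg_scores: np.ndarray,
    grid: SurfaceGrid | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    mode: str = "corrected",
    clade_pair: tuple[str, str] = ("", ""),
) -> OverlapTestResult:
    """Niche equivalency test: pooled occurrences randomly re-assigned.

    Surfaces (and their Silverman bandwidths) are rebuilt from scratch for
    every permuted partition, mirroring exactly the procedure that produced
    the observed overlap.  Lower-tailed: rejects when D_obs is smaller than
    expected under exchangeable occurrences.
    """
    occ_a = np.atleast_2d(np.asarray(occ_a, dtype=float))
    occ_b = np.atleast_2d(np.asarray(occ_b, dtype=float))
    n_a, n_b = len(occ_a), len(occ_b)
    if n_a < 1 or n_b < 1 or n_a + n_b < 2:
        raise ValueError("each clade needs >= 1 occurrence and the pool >= 2")
    bg_scores = np.asarray(bg_scores, dtype=float)
    if grid is None:
        grid = SurfaceGrid.from_scores(bg_scores)

    # availability surface is permutation-invariant: build once, reuse
    ref = occupancy_surface(occ_a, bg_scores, grid=grid, mode=mode)
    e = ref.e
    surf_b = occupancy_surface(occ_b, bg_scores, grid=grid, mode=mode, _bg_density=e)
    d_obs = schoener_d(ref, surf_b)

    pool = np.vstack([occ_a, occ_b])
    # canonical row order makes the null independent of which clade is "A"
    pool = pool[np.lexsort((pool[:, 1], pool[:, 0]))]
    d_sim = np.empty(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        perm = rng.permutation(len(pool))
        pa, pb = pool[perm[:n_a]], pool[perm[n_a:]]
        sa = occupancy_surface(pa, bg_scores, grid=grid, mode=mode, _bg_density=e)
        sb = occupancy_surface(pb, bg_scores, grid=grid, mode=mode, _bg_density=e)
        d_sim[r] = schoener_d(sa, sb)
    p = compare_to_null(d_obs, d_sim, "lower")
    return OverlapTestResult(
        clade_pair=clade_pair,
        d_obs=d_obs,
        d_sim=d_sim,
        tail="lower_tailed_equivalency",
        p_value=p,
        rng_seed=seed,
    )


def significance_code(p: float) -> str:
    """Table annotation: ** for p <= 0.01, * for p < 0.05, NS otherwise."""
    if p <= 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"
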