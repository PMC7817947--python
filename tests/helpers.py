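"""Shared oracles and synthetic-data builders for the test suite.

The oracles here are deliberately naive (exhaustive per-voxel loops, O(N*M)
pairwise distances, affine curve families with known rank) so they stay
independent of the optimized implementations they check.
"""

from __future__ import annotations

import numpy as np

from kbplan.core_grid import StructureMask, VoxelGrid
from kbplan.histograms import CumulativeCurve


def brute_force_dvh_percent(doses: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Percent of voxels with dose >= each edge, by explicit counting."""
    d = np.asarray(doses, dtype=float).ravel()
    return np.array([100.0 * np.sum(d >= e) / d.size for e in edges])


def brute_force_signed_distance(target_occ: np.ndarray, spacing) -> np.ndarray:
    """Signed distance to target-surface voxel centers by exhaustive pairwise
    search.  Surface = mask voxel with >=1 non-mask 6-neighbor inside the
    grid; negative strictly inside, zero on the surface, positive outside."""
    occ = np.asarray(target_occ, dtype=bool)
    sp = np.asarray(spacing, dtype=float)
    shape = occ.shape
    surface = np.zeros(shape, dtype=bool)
    for idx in np.argwhere(occ):
        i, j, k = idx
        for axis, delta in ((0, -1), (0, 1), (1, -1), (1, 1), (2, -1), (2, 1)):
            n = idx.copy()
            n[axis] += delta
            if 0 <= n[axis] < shape[axis] and not occ[tuple(n)]:
                surface[i, j, k] = True
                break
    surf_idx = np.argwhere(surface).astype(float)
    assert surf_idx.size, "degenerate target: no surface voxels"
    coords = np.argwhere(np.ones(shape, dtype=bool)).astype(float)
    deltas = (coords[:, None, :] - surf_idx[None, :, :]) * sp  # (N, M, 3)
    dist = np.sqrt((deltas**2).sum(axis=2)).min(axis=1).reshape(shape)
    out = np.where(occ & ~surface, -dist, dist)
    return out


def random_mask(rng: np.random.Generator, grid: VoxelGrid, p: float = 0.3,
                name: str = "m", role: str = "oar") -> StructureMask:
    occ = rng.random(grid.shape) < p
    if not occ.any():
        occ[tuple(rng.integers(0, s) for s in grid.shape)] = True
    return StructureMask(grid=grid, occupancy=occ, name=name, role=role)


def gaussian_mixture_dvh_family(
    n_curves: int, rng: np.random.Generator, n_points: int = 101
) -> list[CumulativeCurve]:
    """Valid DVH curves spanning an affine family of rank exactly 4.

    Ordinates are 100*(1 - sum_i w_i F_i(d)) for 5 fixed Gaussian CDFs F_i
    and random simplex weights w, so the family is affine of dimension 4 and
    every member is monotone non-increasing within [0, 100].
    """
    x = np.linspace(0.0, 70.0, n_points)
    from scipy.stats import norm

    centers = [15.0, 25.0, 35.0, 45.0, 55.0]
    cdfs = np.stack([norm.cdf(x, loc=c, scale=5.0) for c in centers])
    curves = []
    for _ in range(n_curves):
        w = rng.dirichlet(np.ones(len(centers)))
        ordinate = 100.0 * (1.0 - w @ cdfs)
        curves.append(CumulativeCurve(abscissa=x, ordinate=ordinate, kind="dvh"))
    return curves


def rank1_dvh_family(ts, n_points: int = 101) -> list[CumulativeCurve]:
    """Affine rank-1 DVH family: A + t*(B - A) for valid endpoints A, B."""
    x = np.linspace(0.0, 70.0, n_points)
    a = 100.0 / (1.0 + np.exp((x - 30.0) / 4.0))
    b = 100.0 / (1.0 + np.exp((x - 45.0) / 4.0))
    return [
        CumulativeCurve(abscissa=x, ordinate=a + t * (b - a), kind="dvh")
        for t in np.asarray(ts, dtype=float)
    ]
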