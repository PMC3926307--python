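"""Independent brute-force oracles used to cross-check the production code.

These deliberately avoid the implementation paths under test:
connectivity via an explicit flood fill (no scipy.ndimage.label), nearest
background distances via a KD-tree over background voxel centers (no
distance transform), coverage via an explicit per-voxel containment loop.
"""

from collections import deque

import numpy as np
from scipy.spatial import cKDTree

_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    26: [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
}


def flood_fill(occ: np.ndarray, seed, connectivity: int = 26) -> np.ndarray:
    """Boolean mask of the component of ``seed`` by explicit BFS."""
    occ = np.asarray(occ, dtype=bool)
    out = np.zeros_like(occ)
    if not occ[tuple(seed)]:
        return out
    shape = occ.shape
    q = deque([tuple(seed)])
    out[tuple(seed)] = True
    offsets = _OFFSETS[connectivity]
    while q:
        i, j, k = q.popleft()
        for di, dj, dk in offsets:
            n = (i + di, j + dj, k + dk)
            if (
                0 <= n[0] < shape[0]
                and 0 <= n[1] < shape[1]
                and 0 <= n[2] < shape[2]
                and occ[n]
                and not out[n]
            ):
                out[n] = True
                q.append(n)
    return out


def components(occ: np.ndarray, connectivity: int = 26):
    """All connected components as boolean masks, via repeated flood fill."""
    remaining = np.asarray(occ, dtype=bool).copy()
    comps = []
    while remaining.any():
        seed = np.argwhere(remaining)[0]
        comp = flood_fill(remaining, seed, connectivity)
        comps.append(comp)
        remaining &= ~comp
    return comps


def nearest_background_distances(grid) -> np.ndarray:
    """For every foreground voxel, min distance (mm) to a background voxel center.

    The volume is padded by one background voxel per face, matching the
    boundedness convention of the production distance map.
    """
    occ = np.pad(grid.occupancy, 1, constant_values=False)
    spacing = np.asarray(grid.spacing)
    bg = np.argwhere(~occ) * spacing
    fg = np.argwhere(occ) * spacing
    dists, _ = cKDTree(bg).query(fg, k=1)
    return dists


def brute_force_inscribed(grid, barycenter: np.ndarray):
    """Exhaustive max-min-distance inscribed sphere with the shared tie-breaks.

    Returns (voxel index triple, max distance mm). Ties within 1e-9 are
    broken by distance to the barycenter, then by smallest linear index.
    """
    dists = nearest_background_distances(grid)
    fg = np.argwhere(np.pad(grid.occupancy, 1, constant_values=False)) - 1
    dmax = dists.max()
    cand = fg[dists > dmax - 1e-9]
    world = np.asarray(grid.origin) + cand * np.asarray(grid.spacing)
    d_bc = np.linalg.norm(world - np.asarray(barycenter), axis=1)
    cand = cand[d_bc <= d_bc.min() + 1e-9]
    lin = np.ravel_multi_index(cand.T, grid.shape)
    best = cand[np.argmin(lin)]
    return tuple(int(v) for v in best), float(dmax)


def brute_force_coverage(zone, tumor_indices: np.ndarray, margin_mm: float) -> bool:
    """Per-voxel containment check: every tumor voxel inside with margin."""
    dists = np.full(zone.shape, 0.0)
    occ = zone.occupancy
    fg_d = nearest_background_distances(zone)
    fg = np.argwhere(occ)
    dists[fg[:, 0], fg[:, 1], fg[:, 2]] = fg_d[
        # nearest_background_distances orders foreground by argwhere on the
        # padded array, which matches argwhere order on the unpadded one
        np.arange(len(fg))
    ]
    for i, j, k in tumor_indices:
        if not occ[i, j, k]:
            return False
        if dists[i, j, k] + 1e-9 < margin_mm:
            return False
    return True


def line_mask_extent(grid, point, direction, step_frac: float = 0.1) -> float:
    """Outer extent of the mask along a line, by dense sampling of voxel hits."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    half = float(np.linalg.norm(np.asarray(grid.shape) * np.asarray(grid.spacing)))
    t = np.arange(-half, half, min(grid.spacing) * step_frac)
    pts = np.asarray(point) + t[:, None] * d
    idx = np.rint((pts - np.asarray(grid.origin)) / np.asarray(grid.spacing)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    hit = np.zeros(len(t), bool)
    hit[ok] = grid.occupancy[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    if not hit.any():
        return 0.0
    centers = np.asarray(grid.origin) + idx[hit] * np.asarray(grid.spacing)
    proj = (centers - np.asarray(point)) @ d
    return float(proj.max() - proj.min())


def feret_2d(points: np.ndarray) -> float:
    """Maximal pairwise distance among points (exhaustive)."""
    if len(points) < 2:
        return 0.0
    best = 0.0
    for i in range(len(points) - 1):
        d = np.linalg.norm(points[i + 1 :] - points[i], axis=1).max()
        best = max(best, float(d))
    return best
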