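"""Segmentation-based size and shape metrics of a treatment zone.

The zone's geometric center (barycenter) is the unweighted centroid of the
foreground voxel centers. Principal axes are the eigenvectors of the
covariance of those voxel centers, ordered by descending eigenvalue. The
three axis diameters are chord lengths through the barycenter along the
principal axes, re-labelled long / intermediate / short by realized length.

Two dimensionless shape ratios summarize the ordered diameters:

* circularity  = short / long              (1 = perfectly round)
* sphericity   = long / ((intermediate + short) / 2)

With size-ordered diameters circularity lies in (0, 1] and sphericity >= 1;
both equal 1 exactly for a sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid

__all__ = [
    "AxisDiameters",
    "ShapeMetrics",
    "barycenter",
    "principal_axes",
    "chord_diameter",
    "axis_diameters",
    "circularity",
    "sphericity",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class AxisDiameters:
    """Long / intermediate / short diameters with their directions.

    ``directions`` is a (3, 3) array whose rows are mutually orthonormal unit
    vectors in the world frame, ordered long -> short; all three chords pass
    through ``barycenter``, which is their common intersection point.
    """

    long_mm: float
    intermediate_mm: float
    short_mm: float
    directions: np.ndarray
    barycenter: np.ndarray

    def __post_init__(self) -> None:
        if not (self.long_mm >= self.intermediate_mm >= self.short_mm > 0):
            raise ValueError(
                f"diameters must satisfy long >= intermediate >= short > 0, got "
                f"({self.long_mm}, {self.intermediate_mm}, {self.short_mm})"
            )
        dirs = np.asarray(self.directions, dtype=float)
        if dirs.shape != (3, 3):
            raise ValueError("directions must be a (3, 3) array of row vectors")
        gram = dirs @ dirs.T
        if not np.allclose(gram, np.eye(3), atol=1e-7):
            off = np.abs(gram - np.eye(3)).max()
            raise ValueError(f"directions not orthonormal (max deviation {off:.2e})")
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "barycenter", np.asarray(self.barycenter, dtype=float))

    @classmethod
    def from_lengths(
        cls, long_mm: float, intermediate_mm: float, short_mm: float
    ) -> "AxisDiameters":
        """Build from plain lengths with canonical axes (for tabulated values)."""
        return cls(
            float(long_mm),
            float(intermediate_mm),
            float(short_mm),
            np.eye(3),
            np.zeros(3),
        )

    @property
    def as_tuple(self) -> tuple[float, float, float]:
        return (self.long_mm, self.intermediate_mm, self.short_mm)


@dataclass(frozen=True)
class ShapeMetrics:
    """Dimensionless circularity and sphericity of an ordered diameter triple."""

    circularity: float
    sphericity: float

    @classmethod
    def from_lengths(
        cls, long_mm: float, intermediate_mm: float, short_mm: float
    ) -> "ShapeMetrics":
        if long_mm <= 0 or (intermediate_mm + short_mm) <= 0:
            raise ValueError("diameters must be positive")
        return cls(
            circularity=short_mm / long_mm,
            sphericity=long_mm / ((intermediate_mm + short_mm) / 2.0),
        )

    @classmethod
    def from_diameters(cls, d: AxisDiameters) -> "ShapeMetrics":
        return cls.from_lengths(d.long_mm, d.intermediate_mm, d.short_mm)


def barycenter(grid: VolumeGrid) -> np.ndarray:
    """Geometric center of the zone: mean of foreground voxel-center coordinates."""
    return grid.foreground_world().mean(axis=0)


def principal_axes(grid: VolumeGrid) -> np.ndarray:
    """Principal axes of the foreground voxel cloud, rows ordered by
    descending eigenvalue of the coordinate covariance.

    The sign of each eigenvector is fixed so its largest-magnitude component
    is positive. Near-degenerate eigenvalues (relative gap below 1e-6) are
    ordered lexicographically by vector coordinates so the result is
    deterministic for isotropic shapes.
    """
    coords = grid.foreground_world()
    if len(coords) < 4:
        raise ValueError(f"need at least 4 foreground voxels for PCA, got {len(coords)}")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    vecs = evecs[:, order].T  # rows

    scale = float(evals[0])
    if scale <= 0:
        raise ValueError("degenerate mask: all principal components vanish (single point)")
    for rank, ev in enumerate(evals):
        if ev / scale < 1e-12:
            kind = "collinear" if rank == 1 else "planar"
            raise ValueError(
                f"degenerate mask ({kind}): principal component {rank + 1} vanishes"
            )

    for i in range(3):
        j = int(np.argmax(np.abs(vecs[i])))
        if vecs[i, j] < 0:
            vecs[i] = -vecs[i]

    # deterministic ordering within near-equal eigenvalue groups
    i = 0
    while i < 3:
        j = i + 1
        while j < 3 and (evals[i] - evals[j]) / scale < 1e-6:
            j += 1
        if j - i > 1:
            group = sorted(
                (tuple(np.round(v, 9)) for v in vecs[i:j]), reverse=True
            )
            vecs[i:j] = np.asarray(group)
        i = j
    return vecs


def chord_diameter(
    grid: VolumeGrid, point: np.ndarray, direction: np.ndarray
) -> float:
    """Outer-extent length of the zone along a line through ``point``.

    The line is sampled at a step of a quarter of the smallest voxel size
    over +/- half the grid diagonal; the chord is the distance between the
    projections of the two extreme foreground voxel centers hit by the line
    (center-to-center extent, consistent with the plane-based caliper
    measurements). Interior gaps (indentations) do not shorten the chord --
    they are penalized by the inscribed sphere instead.
    """
    point = np.asarray(point, dtype=float)
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    d = d / norm
    step = min(grid.spacing) / 4.0
    half = float(np.linalg.norm(np.asarray(grid.shape) * np.asarray(grid.spacing))) / 2.0
    t = np.arange(-half, half + step, step)
    pts = point + t[:, None] * d
    hits = grid.contains_points(pts)
    if not hits.any():
        raise ValueError(
            "chord line misses the foreground (reference point may lie outside the zone)"
        )
    hit_pts = pts[hits]
    centers = grid.world_coordinates(grid.world_to_index(hit_pts))
    tproj = (centers - point) @ d
    return float(tproj.max() - tproj.min())


def axis_diameters(grid: VolumeGrid) -> AxisDiameters:
    """Chord diameters through the barycenter along the three principal axes.

    The three chords are re-labelled in decreasing length order, so the
    long/intermediate/short labels reflect realized lengths even where the
    eigenvalue (variance) order disagrees with the chord order.
    """
    bc = barycenter(grid)
    axes = principal_axes(grid)
    lengths = np.array([chord_diameter(grid, bc, axes[i]) for i in range(3)])
    order = np.argsort(lengths)[::-1]
    lengths = lengths[order]
    return AxisDiameters(
        float(lengths[0]), float(lengths[1]), float(lengths[2]), axes[order], bc
    )


def circularity(d: AxisDiameters) -> float:
    """Short over long diameter; 1 indicates perfect roundness."""
    return d.short_mm / d.long_mm


def sphericity(d: AxisDiameters) -> float:
    """Long diameter over the mean of intermediate and short diameters."""
    return d.long_mm / ((d.intermediate_mm + d.short_mm) / 2.0)
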