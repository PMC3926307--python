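"""Automated emulation of standard plane-based CT 3D analysis.

The conventional workflow for treatment-zone measurement uses fixed image
planes: the absolute longest diameter on axial planes, the longest axial
diameter perpendicular to it, and the longest craniocaudal diameter on
coronal planes. The three measurements are ordered by size into long /
intermediate / short diameters; the inscribed-sphere diameter is taken to
equal the short diameter, and the treatable tumor sphere is 2x the safety
margin smaller. The center of the inscribed sphere is not localized by this
workflow, so no barycenter offset exists.

This module automates that manual caliper procedure deterministically:
the axial long diameter is the maximal 2D Feret diameter over axial slices,
the perpendicular diameter is the projection width of the same slice's
foreground perpendicular to it, and the craniocaudal diameter is the global
extent along the craniocaudal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .grid import VolumeGrid
from .geometry import AxisDiameters, ShapeMetrics

__all__ = [
    "AxialMeasurement",
    "TechniqueBReport",
    "axial_long_diameter",
    "axial_perp_diameter",
    "craniocaudal_diameter",
    "technique_b_report",
]


@dataclass(frozen=True)
class AxialMeasurement:
    """An in-plane caliper measurement: length, slice, and world direction."""

    length_mm: float
    slice_index: int
    direction: np.ndarray  # unit vector in the world frame, zero craniocaudal component


@dataclass(frozen=True)
class TechniqueBReport:
    """Plane-based measurements, their size-ordered relabeling, and derived sizes.

    ``shape`` applies the circularity/sphericity equations to the size-ordered
    triple; ``shape_unordered`` applies them with the plane roles kept as
    measured (axial-long as long, axial-perpendicular as intermediate,
    craniocaudal as short), which is how a reader who never re-orders the
    diameters would evaluate them. The barycenter offset is not assessable
    with this technique and is deliberately absent.
    """

    axial_long_mm: float
    axial_perp_mm: float
    craniocaudal_mm: float
    ordered: AxisDiameters
    shape: ShapeMetrics
    shape_unordered: ShapeMetrics
    inscribed_diameter_mm: float
    tumor_diameter_mm: float
    margin_mm: float


def _slice_points(grid: VolumeGrid, k: int) -> np.ndarray:
    """World coordinates of foreground voxel centers in axial slice ``k``."""
    cc = grid.craniocaudal_axis
    sl = [slice(None)] * 3
    sl[cc] = k
    plane = grid.occupancy[tuple(sl)]
    ij = np.argwhere(plane)
    if len(ij) == 0:
        return np.empty((0, 3))
    idx = np.zeros((len(ij), 3), dtype=float)
    a1, a2 = grid.axial_axes
    idx[:, a1] = ij[:, 0]
    idx[:, a2] = ij[:, 1]
    idx[:, cc] = k
    return grid.world_coordinates(idx)


def _boundary_points(grid: VolumeGrid, k: int) -> np.ndarray:
    """Boundary subset of a slice's foreground (4-connectivity within the plane)."""
    cc = grid.craniocaudal_axis
    sl = [slice(None)] * 3
    sl[cc] = k
    plane = grid.occupancy[tuple(sl)]
    if not plane.any():
        return np.empty((0, 3))
    interior = ndi.binary_erosion(plane, ndi.generate_binary_structure(2, 1))
    border = plane & ~interior
    ij = np.argwhere(border)
    idx = np.zeros((len(ij), 3), dtype=float)
    a1, a2 = grid.axial_axes
    idx[:, a1] = ij[:, 0]
    idx[:, a2] = ij[:, 1]
    idx[:, cc] = k
    return grid.world_coordinates(idx)


def axial_long_diameter(grid: VolumeGrid) -> AxialMeasurement:
    """Absolute longest in-plane diameter over all axial slices.

    For each axial slice the maximal pairwise distance between boundary voxel
    centers (2D Feret diameter) is evaluated exhaustively; the overall
    maximum wins, ties going to the lowest slice index. Degenerate
    single-voxel slices measure 0.
    """
    cc = grid.craniocaudal_axis
    n_slices = grid.shape[cc]
    best_len = -1.0
    best_k = -1
    best_dir = None
    for k in range(n_slices):
        pts = _boundary_points(grid, k)
        if len(pts) == 0:
            continue
        if len(pts) == 1:
            length, pair = 0.0, (0, 0)
        else:
            diff = pts[:, None, :] - pts[None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            flat = int(np.argmax(d2))
            pair = np.unravel_index(flat, d2.shape)
            length = float(np.sqrt(d2[pair]))
        if length > best_len + 1e-9:
            best_len = length
            best_k = k
            if length > 0:
                v = pts[pair[1]] - pts[pair[0]]
                best_dir = v / np.linalg.norm(v)
            else:
                d = np.zeros(3)
                d[grid.axial_axes[0]] = 1.0
                best_dir = d
    if best_k < 0:
        raise ValueError("empty grid: no axial slice contains foreground")
    return AxialMeasurement(best_len, best_k, best_dir)


def axial_perp_diameter(
    grid: VolumeGrid, slice_index: int, direction: np.ndarray, same_slice: bool = True
) -> float:
    """Longest axial diameter perpendicular to a given in-plane direction.

    Automated as the width of the slice foreground projected onto the
    in-plane perpendicular of ``direction`` (a caliper squeezed perpendicular
    to the long diameter). With ``same_slice=False`` the width is maximized
    over all axial slices instead of measured on ``slice_index`` only.
    """
    cc = grid.craniocaudal_axis
    cc_unit = np.zeros(3)
    cc_unit[cc] = 1.0
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    perp = np.cross(cc_unit, d)
    perp /= np.linalg.norm(perp)

    def width(k: int) -> float:
        pts = _slice_points(grid, k)
        if len(pts) == 0:
            return -1.0
        proj = pts @ perp
        return float(proj.max() - proj.min())

    if same_slice:
        w = width(slice_index)
        if w < 0:
            raise ValueError(f"axial slice {slice_index} contains no foreground")
        return w
    return max(width(k) for k in range(grid.shape[cc]))


def craniocaudal_diameter(grid: VolumeGrid) -> float:
    """Longest craniocaudal extent of the zone (as read off coronal planes).

    Equals the global Feret extent of the mask along the craniocaudal axis.
    """
    cc = grid.craniocaudal_axis
    idx = grid.foreground_indices()[:, cc]
    return float((idx.max() - idx.min()) * grid.spacing[cc])


def technique_b_report(
    grid: VolumeGrid, margin_mm: float = 5.0, same_slice: bool = True
) -> TechniqueBReport:
    """Full plane-based analysis of a zone.

    Measures the three plane diameters, orders them by size into
    long/intermediate/short, evaluates the shape ratios on the ordered triple
    (and on the unordered plane-role triple for comparability), equates the
    inscribed-sphere diameter with the short diameter, and derives the
    treatable tumor sphere by subtracting twice the safety margin.
    """
    if margin_mm < 0:
        raise ValueError(f"safety margin must be non-negative, got {margin_mm}")
    axial = axial_long_diameter(grid)
    perp = axial_perp_diameter(grid, axial.slice_index, axial.direction, same_slice)
    cc_len = craniocaudal_diameter(grid)

    cc = grid.craniocaudal_axis
    cc_unit = np.zeros(3)
    cc_unit[cc] = 1.0
    perp_dir = np.cross(cc_unit, axial.direction)
    perp_dir /= np.linalg.norm(perp_dir)

    lengths = np.array([axial.length_mm, perp, cc_len])
    dirs = np.stack([axial.direction, perp_dir, cc_unit])
    order = np.argsort(lengths)[::-1]
    lengths_sorted = lengths[order]
    bc = grid.foreground_world().mean(axis=0)
    ordered = AxisDiameters(
        float(lengths_sorted[0]),
        float(lengths_sorted[1]),
        float(lengths_sorted[2]),
        dirs[order],
        bc,
    )
    shape = ShapeMetrics.from_diameters(ordered)
    shape_unordered = ShapeMetrics.from_lengths(axial.length_mm, perp, cc_len)
    inscribed = ordered.short_mm
    tumor = max(0.0, inscribed - 2.0 * margin_mm)
    return TechniqueBReport(
        axial_long_mm=axial.length_mm,
        axial_perp_mm=perp,
        craniocaudal_mm=cc_len,
        ordered=ordered,
        shape=shape,
        shape_unordered=shape_unordered,
        inscribed_diameter_mm=inscribed,
        tumor_diameter_mm=tumor,
        margin_mm=float(margin_mm),
    )
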