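"""Synthetic treatment-zone phantoms with analytic ground truth.

Electroporation with multiple parallel needle applicators produces zones
that expand between the applicator pairs and merge into one overlapping,
often indented body, 1-5 cm across; thermal ablation with a single needle
produces ellipsoid-like zones. The generators here voxelize idealized
versions of both onto an anisotropic lattice (canonical spacing
1 x 1 x 0.5 mm, matching 1 mm axial reconstructions with 0.5 mm overlap),
and every phantom ships a truth record with its analytically known
diameters, inscribed-sphere size and center offset, so recovery of those
values by the measurement code can be asserted at voxel tolerance.

Kinds
-----
sphere, ellipsoid
    Convex references with fully closed-form truth.
notched_sphere
    Sphere of radius R minus a cylinder of radius r through its center: the
    canonical indented zone. Its largest inscribed sphere has radius
    (R - r) / 2 centered at distance (R + r) / 2 from the sphere center,
    perpendicular to the notch axis, so eccentricity truth is analytic too.
dumbbell
    Two spheres joined by a thin capsule bridge: tests outer-extent chord
    semantics across an interior waist.
multi_applicator
    Union of capsule slabs spanning applicator pairs (parallel needles along
    the craniocaudal axis with a given tip exposure). A seeded per-pair
    lobe-radius jitter produces the surface indentations of merged in-vivo
    zones; jitter 0 gives a smooth, nearly convex body.

All generation is deterministic: the same :class:`PhantomSpec` (including
its seed) always regenerates a bit-identical mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

from .grid import VolumeGrid

__all__ = [
    "PhantomSpec",
    "make_sphere",
    "make_ellipsoid",
    "make_notched_sphere",
    "make_dumbbell",
    "make_multi_applicator",
    "make_phantom",
    "triangle_positions",
    "paired_row_positions",
    "protocol_spec",
]

DEFAULT_SPACING = (1.0, 1.0, 0.5)
_SHELL = 4  # background voxels kept around every phantom

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class PhantomSpec:
    """Serializable recipe for one phantom mask.

    ``params`` holds the kind-specific geometry in mm. ``grid_shape`` of
    ``None`` auto-sizes the lattice to the phantom plus a background shell.
    """

    kind: str
    params: dict
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    grid_shape: tuple[int, int, int] | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spacing"] = list(self.spacing)
        d["grid_shape"] = list(self.grid_shape) if self.grid_shape else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(
            kind=d["kind"],
            params=dict(d["params"]),
            spacing=tuple(d.get("spacing", DEFAULT_SPACING)),
            grid_shape=tuple(d["grid_shape"]) if d.get("grid_shape") else None,
            seed=int(d.get("seed", 0)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        return cls.from_dict(json.loads(text))

    @classmethod
    def load(cls, path) -> "PhantomSpec":
        """Load a spec from a JSON or YAML config file."""
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_json(text)


def _grid_axes(half_extent, spacing, center, grid_shape):
    """Per-axis voxel-center coordinate arrays with the phantom centered."""
    axes = []
    shape = []
    for a in range(3):
        if grid_shape is None:
            n_half = int(np.ceil(half_extent[a] / spacing[a])) + _SHELL
            n = 2 * n_half + 1
        else:
            n = int(grid_shape[a])
        shape.append(n)
        axes.append(center[a] + (np.arange(n) - (n - 1) / 2.0) * spacing[a])
    return axes, tuple(shape)


def _check_shell(occ: np.ndarray, what: str) -> None:
    for a in range(3):
        edge = [slice(None)] * 3
        for s in (slice(0, 2), slice(-2, None)):
            edge[a] = s
            if occ[tuple(edge)].any():
                raise ValueError(f"{what} exceeds the grid (needs a 2-voxel background shell)")


def _finish(occ, axes, spacing, what):
    _check_shell(occ, what)
    origin = tuple(float(ax[0]) for ax in axes)
    return VolumeGrid(occ, tuple(float(s) for s in spacing), origin)


def make_sphere(
    radius_mm: float,
    spacing=DEFAULT_SPACING,
    center=(0.0, 0.0, 0.0),
    grid_shape=None,
):
    """Digitized sphere; truth: all diameters 2r, inscribed 2r, offset 0."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    axes, _ = _grid_axes([radius_mm] * 3, spacing, center, grid_shape)
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    occ = d2 <= radius_mm**2
    grid = _finish(occ, axes, spacing, "sphere")
    truth = {
        "kind": "sphere",
        "diameters_mm": (2 * radius_mm,) * 3,
        "inscribed_diameter_mm": 2 * radius_mm,
        "barycenter_offset_mm": 0.0,
        "center": tuple(center),
        "volume_mm3": 4.0 / 3.0 * np.pi * radius_mm**3,
    }
    return grid, truth


def _rotation_matrix(rotation) -> np.ndarray:
    if rotation is None:
        return np.eye(3)
    if np.isscalar(rotation):
        # degrees about the craniocaudal (z) axis
        t = np.deg2rad(float(rotation))
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be an angle in degrees or an orthogonal 3x3 matrix")
    return R


def make_ellipsoid(
    semi_axes_mm,
    rotation=None,
    spacing=DEFAULT_SPACING,
    center=(0.0, 0.0, 0.0),
    grid_shape=None,
):
    """Digitized (optionally rotated) ellipsoid.

    Truth: sorted diameters (2a, 2b, 2c), inscribed diameter 2*min(semi-axes),
    circularity c/a, sphericity 2a/(b+c) -- all invariant under the rotation.
    """
    a = np.asarray(semi_axes_mm, dtype=float)
    if a.shape != (3,) or (a <= 0).any():
        raise ValueError("semi_axes_mm must be three positive lengths")
    R = _rotation_matrix(rotation)
    half = np.sqrt(((R * a) ** 2).sum(axis=1))  # extent of rotated ellipsoid per axis
    axes, _ = _grid_axes(half, spacing, center, grid_shape)
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    # body-frame coordinates: R^T (x - c)
    u = R[0, 0] * dx + R[1, 0] * dy + R[2, 0] * dz
    v = R[0, 1] * dx + R[1, 1] * dy + R[2, 1] * dz
    w = R[0, 2] * dx + R[1, 2] * dy + R[2, 2] * dz
    occ = (u / a[0]) ** 2 + (v / a[1]) ** 2 + (w / a[2]) ** 2 <= 1.0
    grid = _finish(occ, axes, spacing, "ellipsoid")
    srt = np.sort(a)[::-1]
    truth = {
        "kind": "ellipsoid",
        "diameters_mm": tuple(2 * srt),
        "inscribed_diameter_mm": 2 * float(srt[2]),
        "barycenter_offset_mm": 0.0,
        "center": tuple(center),
        "circularity": float(srt[2] / srt[0]),
        "sphericity": float(2 * srt[0] / (srt[1] + srt[2])),
        "volume_mm3": 4.0 / 3.0 * np.pi * float(np.prod(a)),
    }
    return grid, truth


def make_notched_sphere(
    radius_mm: float,
    notch_radius_mm: float,
    notch_axis: str = "x",
    through: bool = True,
    spacing=DEFAULT_SPACING,
    center=(0.0, 0.0, 0.0),
    grid_shape=None,
):
    """Sphere with a cylindrical notch drilled along one axis.

    The notch models an indentation (e.g. a spared vessel) limiting the
    zone's usable core. With ``through=True`` (default) an infinite cylinder
    of the notch radius is removed through the sphere center: the largest
    inscribed sphere shrinks to diameter ``R - r_notch``, its center sitting
    ``(R + r_notch) / 2`` off the sphere center perpendicular to the notch
    axis (the barycenter itself lands in the void, so axis chords through it
    are undefined -- the specified error case). With ``through=False`` the
    cylinder is drilled from the +axis surface only down to the center: the
    largest inscribed sphere then has diameter ``R`` centered ``R / 2``
    down the -axis direction, and the barycenter stays inside tissue so the
    full technique-A analysis applies.
    """
    if not 0 <= notch_radius_mm < radius_mm:
        raise ValueError("need 0 <= notch_radius < radius")
    axes, _ = _grid_axes([radius_mm] * 3, spacing, center, grid_shape)
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
    d = [x - center[0], y - center[1], z - center[2]]
    occ = d[0] ** 2 + d[1] ** 2 + d[2] ** 2 <= radius_mm**2
    ax = _AXIS_INDEX[notch_axis]
    if notch_radius_mm > 0:
        perp = [d[i] for i in range(3) if i != ax]
        in_cyl = perp[0] ** 2 + perp[1] ** 2 <= notch_radius_mm**2
        if not through:
            in_cyl = in_cyl & (d[ax] >= 0)
        occ = occ & ~in_cyl
    grid = _finish(occ, axes, spacing, "notched sphere")
    if notch_radius_mm == 0:
        inscribed, offset = 2 * radius_mm, 0.0
    elif through:
        # ball at in-plane distance t from the axis: radius min(R - t, t - r)
        inscribed = radius_mm - notch_radius_mm
        offset = (radius_mm + notch_radius_mm) / 2.0
    else:
        # ball at depth t down the -axis: radius min(R - t, t), optimum t = R/2
        inscribed = radius_mm
        offset = radius_mm / 2.0
    truth = {
        "kind": "notched_sphere",
        "outer_diameter_mm": 2 * radius_mm,
        "inscribed_diameter_mm": float(inscribed),
        # distance of the Chebyshev center from the *sphere* center; the
        # barycenter offset differs only by the small centroid shift
        "chebyshev_radial_distance_mm": float(offset),
        "center": tuple(center),
    }
    return grid, truth


def make_dumbbell(
    lobe_radius_mm: float,
    separation_mm: float,
    bridge_radius_mm: float,
    axis: str = "x",
    spacing=DEFAULT_SPACING,
    center=(0.0, 0.0, 0.0),
    grid_shape=None,
):
    """Two spheres joined by a thin capsule bridge along one axis.

    Truth: outer extent along the axis is separation + 2 * lobe radius; the
    interior waist must not shorten outer-extent chords through it.
    """
    if bridge_radius_mm <= 0 or lobe_radius_mm <= 0 or separation_mm <= 0:
        raise ValueError("all dumbbell dimensions must be positive")
    ax = _AXIS_INDEX[axis]
    half = np.full(3, max(lobe_radius_mm, bridge_radius_mm), dtype=float)
    half[ax] = separation_mm / 2.0 + lobe_radius_mm
    axes, _ = _grid_axes(half, spacing, center, grid_shape)
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
    d = [x - center[0], y - center[1], z - center[2]]
    along = d[ax]
    perp = [d[i] for i in range(3) if i != ax]
    perp2 = perp[0] ** 2 + perp[1] ** 2
    h = separation_mm / 2.0
    lobes = ((along - h) ** 2 + perp2 <= lobe_radius_mm**2) | (
        (along + h) ** 2 + perp2 <= lobe_radius_mm**2
    )
    clamped = np.clip(along, -h, h)
    bridge = (along - clamped) ** 2 + perp2 <= bridge_radius_mm**2
    grid = _finish(lobes | bridge, axes, spacing, "dumbbell")
    truth = {
        "kind": "dumbbell",
        "long_diameter_mm": separation_mm + 2 * lobe_radius_mm,
        "inscribed_diameter_mm": 2 * lobe_radius_mm,
        "center": tuple(center),
    }
    return grid, truth


def make_multi_applicator(
    applicator_positions,
    tip_exposure_mm: float,
    lobe_radius_mm: float = 9.0,
    spacing=DEFAULT_SPACING,
    center=(0.0, 0.0, 0.0),
    grid_shape=None,
    connect_max_mm: float | None = None,
    radius_jitter: float = 0.0,
    seed: int = 0,
):
    """Merged multi-applicator zone: union of capsule slabs between pairs.

    Applicators are parallel needles along the craniocaudal (z) axis at the
    given in-plane (x, y) offsets from ``center``, active over a segment of
    length ``tip_exposure_mm`` centered on the zone. For every applicator
    pair closer than ``connect_max_mm`` (all pairs when ``None``) the zone
    contains all points within the pair's lobe radius of the vertical
    rectangle spanning the two active segments -- a capsule slab. With
    ``radius_jitter`` > 0 each slab's radius is drawn (seeded) from
    ``lobe_radius * [1 - jitter, 1]``, producing indented merged zones.

    Truth covers connectivity and bounding extents only; inscribed-sphere
    truth for these shapes comes from the brute-force oracle at test time.
    """
    pos = np.asarray(applicator_positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2 or len(pos) < 2:
        raise ValueError("need at least 2 applicators as (n, 2) in-plane positions")
    if tip_exposure_mm <= 0 or lobe_radius_mm <= 0:
        raise ValueError("tip exposure and lobe radius must be positive")
    if not 0 <= radius_jitter < 1:
        raise ValueError("radius_jitter must lie in [0, 1)")

    pairs = []
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            dist = float(np.linalg.norm(pos[j] - pos[i]))
            if connect_max_mm is None or dist <= connect_max_mm:
                pairs.append((i, j))
    if not pairs:
        raise ValueError("no applicator pair within connect_max_mm")

    rng = np.random.default_rng(seed)
    radii = lobe_radius_mm * (1.0 - radius_jitter * rng.random(len(pairs)))

    half_xy = np.abs(pos).max(axis=0) + lobe_radius_mm
    half = np.array([half_xy[0], half_xy[1], tip_exposure_mm / 2.0 + lobe_radius_mm])
    axes, shape = _grid_axes(half, spacing, center, grid_shape)
    xs, ys, zs = axes

    # in-plane distance to a pair's segment and z distance to the active
    # segment are independent, so the 3D capsule-slab test separates
    dz = np.maximum(np.abs(zs - center[2]) - tip_exposure_mm / 2.0, 0.0)
    X, Y = np.meshgrid(xs - center[0], ys - center[1], indexing="ij")
    occ = np.zeros(shape, dtype=bool)
    for (i, j), r in zip(pairs, radii):
        p, q = pos[i], pos[j]
        e = q - p
        ee = float(e @ e)
        if ee == 0:
            u = np.zeros_like(X)
        else:
            u = np.clip(((X - p[0]) * e[0] + (Y - p[1]) * e[1]) / ee, 0.0, 1.0)
        dx = X - (p[0] + u * e[0])
        dy = Y - (p[1] + u * e[1])
        d2_plane = dx**2 + dy**2
        occ |= d2_plane[:, :, None] + (dz**2)[None, None, :] <= r**2

    grid = _finish(occ, axes, spacing, "multi-applicator zone")
    n_comp = int(ndi.label(grid.occupancy, ndi.generate_binary_structure(3, 3))[1])
    if n_comp > 1:
        warnings.warn(
            f"multi-applicator configuration produced {n_comp} disconnected components",
            stacklevel=2,
        )
    truth = {
        "kind": "multi_applicator",
        "n_applicators": int(len(pos)),
        "connected": n_comp == 1,
        "craniocaudal_extent_mm": tip_exposure_mm + 2 * float(radii.max()),
        "inplane_extent_mm": tuple(
            float(pos[:, k].max() - pos[:, k].min() + 2 * radii.max()) for k in (0, 1)
        ),
        "center": tuple(center),
    }
    return grid, truth


_MAKERS = {
    "sphere": make_sphere,
    "ellipsoid": make_ellipsoid,
    "notched_sphere": make_notched_sphere,
    "dumbbell": make_dumbbell,
    "multi_applicator": make_multi_applicator,
}


def make_phantom(spec: PhantomSpec):
    """Build the mask and truth record described by a :class:`PhantomSpec`."""
    if spec.kind not in _MAKERS:
        raise ValueError(f"unknown phantom kind {spec.kind!r}; choose from {sorted(_MAKERS)}")
    kwargs = dict(spec.params)
    if spec.kind == "multi_applicator":
        kwargs.setdefault("seed", spec.seed)
    return _MAKERS[spec.kind](
        spacing=spec.spacing, grid_shape=spec.grid_shape, **kwargs
    )


# -- applicator layouts ---------------------------------------------------


def triangle_positions(side_mm: float) -> list[list[float]]:
    """Three applicators on an equilateral triangle of the given side."""
    r = side_mm / np.sqrt(3.0)
    ang = np.deg2rad([90.0, 210.0, 330.0])
    return [[float(r * np.cos(a)), float(r * np.sin(a))] for a in ang]


def paired_row_positions(
    n_pairs: int, within_pair_mm: float, pair_spacing_mm: float
) -> list[list[float]]:
    """Pairs of applicators in a row: pair i at x = (i - (n-1)/2) * spacing."""
    out = []
    for i in range(n_pairs):
        x = (i - (n_pairs - 1) / 2.0) * pair_spacing_mm
        out.append([float(x), -within_pair_mm / 2.0])
        out.append([float(x), within_pair_mm / 2.0])
    return out


def protocol_spec(
    protocol: int,
    spacing=DEFAULT_SPACING,
    seed: int = 0,
    lobe_radius_mm: float = 9.0,
    radius_jitter: float = 0.25,
) -> PhantomSpec:
    """Phantom recipes mirroring the three in-vivo electroporation protocols.

    Protocols 1 and 2 use three applicators on an equilateral triangle
    (15 mm / 20 mm side) with 20 mm / 25 mm tip exposure. Protocol 3 uses
    six applicators as three parallel pairs (15 mm within a pair, pair
    centers 22.5 mm apart) with 30 mm exposure, capsules formed only between
    applicators up to 23 mm apart so the merged zone keeps its waists. The
    default lobe radius (9 mm) and per-capsule radius jitter (0.25) emulate
    the scale and surface irregularity of the corresponding in-vivo zones.
    """
    if protocol == 1:
        params = {
            "applicator_positions": triangle_positions(15.0),
            "tip_exposure_mm": 20.0,
            "lobe_radius_mm": lobe_radius_mm,
            "radius_jitter": radius_jitter,
        }
    elif protocol == 2:
        params = {
            "applicator_positions": triangle_positions(20.0),
            "tip_exposure_mm": 25.0,
            "lobe_radius_mm": lobe_radius_mm,
            "radius_jitter": radius_jitter,
        }
    elif protocol == 3:
        params = {
            "applicator_positions": paired_row_positions(3, 15.0, 22.5),
            "tip_exposure_mm": 30.0,
            "lobe_radius_mm": lobe_radius_mm,
            "radius_jitter": radius_jitter,
            "connect_max_mm": 23.0,
        }
    else:
        raise ValueError(f"protocol must be 1, 2 or 3, got {protocol}")
    return PhantomSpec("multi_applicator", params, spacing=tuple(spacing), seed=seed)
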