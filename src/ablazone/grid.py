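"""Volumetric binary masks on a regular anisotropic lattice.

The segmented treatment zone is represented as a :class:`VolumeGrid`: a 3D
boolean occupancy array together with per-axis voxel spacing (mm) and the
world position of voxel (0, 0, 0). World coordinates follow the voxel-center
convention: voxel ``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``.

Axis *roles* abstract the anatomical orientation: two lattice axes span the
axial (transverse) image plane and one runs craniocaudally (superior to
inferior). Plane-based standard measurements need that distinction; the
segmentation-based metrics do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

AXIAL_1 = "axial-plane-1"
AXIAL_2 = "axial-plane-2"
CRANIOCAUDAL = "craniocaudal"

_DEFAULT_ROLES = (AXIAL_1, AXIAL_2, CRANIOCAUDAL)

_CONN_STRUCTS = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


class EmptyMaskError(ValueError):
    """Raised when a mask contains no foreground voxels."""


@dataclass(frozen=True)
class VolumeGrid:
    """Binary occupancy lattice with world-frame metadata.

    Parameters
    ----------
    occupancy
        3D boolean array, index order ``(i, j, k)``.
    spacing
        Voxel size per lattice axis in mm, all strictly positive.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    axis_roles
        Anatomical role of each lattice axis; exactly one axis must be
        craniocaudal. Default: axis 2.
    """

    occupancy: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_roles: tuple[str, str, str] = _DEFAULT_ROLES

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError(f"occupancy must be 3D, got ndim={occ.ndim}")
        if occ.dtype != bool:
            uniq = np.unique(occ)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("occupancy must be strictly binary")
            occ = occ.astype(bool)
        object.__setattr__(self, "occupancy", occ)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing must be three positive finite values, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(origin) != 3 or not all(np.isfinite(o) for o in origin):
            raise ValueError(f"origin must be three finite values, got {self.origin}")
        object.__setattr__(self, "origin", origin)
        roles = tuple(self.axis_roles)
        if sorted(roles) != sorted(_DEFAULT_ROLES):
            raise ValueError(f"axis_roles must be a permutation of {_DEFAULT_ROLES}")
        object.__setattr__(self, "axis_roles", roles)
        if not occ.any():
            raise EmptyMaskError("empty mask: no foreground voxels")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def craniocaudal_axis(self) -> int:
        return self.axis_roles.index(CRANIOCAUDAL)

    @property
    def axial_axes(self) -> tuple[int, int]:
        cc = self.craniocaudal_axis
        return tuple(a for a in range(3) if a != cc)  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def foreground_count(self) -> int:
        return int(self.occupancy.sum())

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel-center positions for integer indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index for world points (may fall outside the grid)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.rint((pts - np.asarray(self.origin)) / np.asarray(self.spacing)).astype(int)

    def foreground_indices(self) -> np.ndarray:
        return np.argwhere(self.occupancy)

    def foreground_world(self) -> np.ndarray:
        """(N, 3) world coordinates of all foreground voxel centers."""
        return self.world_coordinates(self.foreground_indices())

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """Boolean foreground membership of world points (nearest-voxel rule)."""
        idx = self.world_to_index(points)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)
        out = np.zeros(len(idx), dtype=bool)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.occupancy[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def with_occupancy(self, occupancy: np.ndarray) -> "VolumeGrid":
        return replace(self, occupancy=occupancy)

    def same_lattice(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


# -- file I/O -------------------------------------------------------------


def _nifti_suffix(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_mask(path: str | Path, threshold: float = 0.5) -> VolumeGrid:
    """Read a NIfTI-1 or NRRD volume and binarize it into a :class:`VolumeGrid`.

    Voxels with value strictly greater than ``threshold`` become foreground.
    Spacing and origin are taken from the header; the craniocaudal axis is the
    lattice axis whose direction is closest to the world superior-inferior
    axis. Rotational components of the header orientation are ignored (the
    lattice is treated as world-axis-aligned), which is adequate for
    axially reconstructed CT segmentations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _nifti_suffix(path):
        data, spacing, origin, zdir = _read_nifti(path)
    elif path.suffix.lower() == ".nrrd":
        data, spacing, origin, zdir = _read_nrrd(path)
    else:
        raise ValueError(f"unsupported mask format: {path.name} (expected .nii, .nii.gz or .nrrd)")

    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"invalid voxel spacing {spacing} in {path}")
    occ = np.asarray(data) > threshold
    if not occ.any():
        raise EmptyMaskError(f"empty mask: no voxel above threshold {threshold} in {path}")
    cc_axis = int(np.argmax(np.abs(zdir)))
    roles = [AXIAL_1, AXIAL_2]
    axis_roles = tuple(
        CRANIOCAUDAL if a == cc_axis else roles.pop(0) for a in range(3)
    )
    return VolumeGrid(occ, tuple(spacing), tuple(origin), axis_roles)  # type: ignore[arg-type]


def _read_nifti(path: Path):
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    affine = img.affine
    origin = affine[:3, 3]
    # world z (superior-inferior in RAS) contribution of each lattice axis
    zdir = affine[2, :3]
    if not np.allclose(zooms, np.linalg.norm(affine[:3, :3], axis=0), atol=1e-3):
        warnings.warn(
            f"{path.name}: affine column norms disagree with header zooms; using zooms",
            stacklevel=3,
        )
    return data, [float(z) for z in zooms], [float(o) for o in origin], zdir


def _read_nrrd(path: Path):
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {img.GetDimension()}D")
    # SimpleITK arrays are indexed (k, j, i); transpose to lattice order (i, j, k)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = [float(s) for s in img.GetSpacing()]
    origin = [float(o) for o in img.GetOrigin()]
    d = np.asarray(img.GetDirection()).reshape(3, 3)
    zdir = d[2, :]
    return data, spacing, origin, zdir


def write_mask(grid: VolumeGrid, path: str | Path) -> None:
    """Write a :class:`VolumeGrid` as a 0/1 label volume (NIfTI-1 or NRRD).

    The written header records the grid's spacing and origin with an
    axis-aligned orientation, so ``read_mask(write_mask(g))`` reproduces the
    occupancy, spacing and origin exactly.
    """
    path = Path(path)
    data = grid.occupancy.astype(np.uint8)
    if _nifti_suffix(path):
        import nibabel as nib

        affine = np.diag(list(grid.spacing) + [1.0])
        affine[:3, 3] = grid.origin
        nib.save(nib.Nifti1Image(data, affine), str(path))
    elif path.suffix.lower() == ".nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data.transpose(2, 1, 0))
        img.SetSpacing(grid.spacing)
        img.SetOrigin(grid.origin)
        sitk.WriteImage(img, str(path), useCompression=False)
    else:
        raise ValueError(f"unsupported mask format: {path.name} (expected .nii, .nii.gz or .nrrd)")


def largest_component(grid: VolumeGrid, connectivity: int = 26) -> VolumeGrid:
    """Keep only the largest connected foreground component.

    A multi-electrode treatment is expected to merge into one overlapping
    zone; stray disconnected islands (segmentation noise) are dropped with a
    warning. Ties on component size are broken by the component containing
    the smallest linear (C-order flattened) voxel index.
    """
    if connectivity not in _CONN_STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_CONN_STRUCTS)}, got {connectivity}")
    labels, n = ndi.label(grid.occupancy, structure=_CONN_STRUCTS[connectivity])
    if n <= 1:
        return grid
    warnings.warn(
        f"mask has {n} connected components; keeping the largest", stacklevel=2
    )
    flat = labels.ravel()
    sizes = np.bincount(flat)[1:]  # skip background
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        # tie: earliest first occurrence in linear index order
        first = {lab: int(np.argmax(flat == lab)) for lab in best}
        keep = min(best, key=lambda lab: first[lab])
    else:
        keep = int(best[0])
    return grid.with_occupancy(labels == keep)
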