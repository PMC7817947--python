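"""Voxel-grid containers for structures and dose.

Everything downstream (histograms, feature extraction, plan scoring) operates
on a single axis-aligned regular lattice.  The convention throughout the
package: voxel indices are 0-based, physical positions refer to voxel
*centers*, and structure masks are resampled onto the dose grid before any
histogram is taken, so that every dose-volume index is evaluated on
dose-native voxels.  Masks are binary; partial-volume effects are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Union

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "DoseGrid",
    "structure_volume",
    "resample_to_grid",
]

Role = Literal["target", "oar", "external"]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular axis-aligned 3-D lattice.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    spacing
        Voxel pitch in mm along each axis; all entries must be positive.
    origin
        Physical position in mm of the *center* of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("VoxelGrid is three-dimensional")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Physical center coordinates (mm) of the voxels along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Bounding box (mm) of voxel centers: ``(low, high)`` per axis."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def center_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (``indexing='ij'``) of voxel-center coordinates in mm."""
        ax = [self.axis_coordinates(a) for a in range(3)]
        return tuple(np.meshgrid(*ax, indexing="ij"))  # type: ignore[return-value]

    def physical_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of physical points (mm), shape (..., 3)."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class StructureMask:
    """Binary occupancy of one anatomical structure on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    occupancy: np.ndarray
    name: str = ""
    role: Role = "oar"

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != self.grid.shape:
            raise ValueError(
                f"occupancy shape {self.occupancy.shape} != grid shape {self.grid.shape}"
            )
        if self.role not in ("target", "oar", "external"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.occupancy))

    def is_empty(self) -> bool:
        return self.voxel_count == 0


@dataclass
class DoseGrid:
    """Absorbed dose in Gy per voxel, with the plan-level prescription dose."""

    grid: VoxelGrid
    dose: np.ndarray
    prescription: float

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {self.dose.shape} != grid shape {self.grid.shape}"
            )
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative everywhere")
        if not self.prescription > 0:
            raise ValueError(f"prescription must be > 0, got {self.prescription}")


def structure_volume(mask: StructureMask) -> float:
    """Volume of a structure in cc (occupied voxels x voxel volume).

    An empty mask yields 0.0; callers that require a non-empty structure must
    check themselves.
    """
    return mask.voxel_count * mask.grid.voxel_volume_cc


def mask_union(masks: list[StructureMask], name: str = "union") -> StructureMask:
    """Voxelwise union of masks sharing a grid."""
    if not masks:
        raise ValueError("mask_union requires at least one mask")
    grid = masks[0].grid
    occ = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        if m.grid != grid:
            raise ValueError("all masks must share one grid")
        occ |= m.occupancy
    return StructureMask(grid=grid, occupancy=occ, name=name, role=masks[0].role)


_SIX_NEIGHBORHOOD = ndimage.generate_binary_structure(3, 1)


def surface_voxels(mask: StructureMask) -> np.ndarray:
    """Boolean array of mask voxels with at least one non-mask 6-neighbor.

    Neighbors outside the grid do not count (``border_value=1`` in the
    erosion), so a structure touching the grid edge is not surface there.
    """
    occ = mask.occupancy
    interior = ndimage.binary_erosion(
        occ, structure=_SIX_NEIGHBORHOOD, border_value=1
    )
    return occ & ~interior


def signed_distance_to_surface(mask: StructureMask) -> np.ndarray:
    """Signed Euclidean distance (mm) from every voxel center to the nearest
    surface-voxel center of ``mask``.

    Negative strictly inside the structure, zero on surface voxels, positive
    outside.  Computed with one exact Euclidean distance transform on the
    complement of the surface set, which by construction equals the minimum
    over all surface-voxel centers.
    """
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty; distance undefined")
    surf = surface_voxels(mask)
    if not surf.any():
        raise ValueError(
            f"mask {mask.name!r} fills the whole grid; surface undefined"
        )
    dist = ndimage.distance_transform_edt(~surf, sampling=mask.grid.spacing)
    sd = np.asarray(dist, dtype=float)
    sd[mask.occupancy & ~surf] *= -1.0
    return sd


MaskOrDose = Union[StructureMask, DoseGrid]


def resample_to_grid(src: MaskOrDose, dst: VoxelGrid) -> MaskOrDose:
    """Resample a mask (nearest-neighbor) or dose (trilinear) onto ``dst``.

    Sampling positions outside the source extent clamp to the nearest source
    voxel, so trilinear output never leaves the source ``[min, max]`` range.
    Raises ``ValueError`` if the two grids do not overlap spatially.
    """
    src_grid = src.grid
    if src_grid == dst:
        if isinstance(src, StructureMask):
            return replace(src, occupancy=src.occupancy.copy())
        return replace(src, dose=src.dose.copy())

    lo_s, hi_s = src_grid.extent()
    lo_d, hi_d = dst.extent()
    if np.any(np.maximum(lo_s, lo_d) > np.minimum(hi_s, hi_d)):
        raise ValueError("source and destination grids have no spatial overlap")

    # fractional source indices of destination voxel centers, per axis
    coords = [
        (dst.axis_coordinates(a) - src_grid.origin[a]) / src_grid.spacing[a]
        for a in range(3)
    ]
    ii, jj, kk = np.meshgrid(*coords, indexing="ij")
    sample = np.stack([ii, jj, kk])

    if isinstance(src, StructureMask):
        out = ndimage.map_coordinates(
            src.occupancy.astype(np.uint8), sample, order=0, mode="nearest"
        )
        return StructureMask(
            grid=dst, occupancy=out.astype(bool), name=src.name, role=src.role
        )
    out = ndimage.map_coordinates(src.dose, sample, order=1, mode="nearest")
    return DoseGrid(grid=dst, dose=out, prescription=src.prescription)
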