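"""Volumetric file I/O: NIfTI and NRRD volumes, plus an optional DICOM-RT
reader (RTSTRUCT contours rasterized per slice, RTDOSE with its grid
scaling).

Volumes are treated as axis-aligned: orientation matrices are reduced to
per-axis spacing and an origin; oblique acquisitions are out of scope.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .core_grid import DoseGrid, StructureMask, VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "read_dose",
    "write_mask",
    "write_dose",
    "read_rtstruct",
    "read_rtdose",
]


def _nifti_grid(img) -> VoxelGrid:
    affine = img.affine
    spacing = tuple(float(s) for s in np.linalg.norm(affine[:3, :3], axis=0))
    origin = tuple(float(o) for o in affine[:3, 3])
    return VoxelGrid(shape=tuple(img.shape[:3]), spacing=spacing, origin=origin)


def read_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a ``.nii``/``.nii.gz`` or ``.nrrd`` volume as (array, grid)."""
    p = Path(path)
    if p.suffix == ".nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(p))
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # zyx -> xyz
        grid = VoxelGrid(
            shape=arr.shape,
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
        )
        return np.asarray(arr), grid
    import nibabel as nib

    img = nib.load(str(p))
    return np.asarray(img.dataobj), _nifti_grid(img)


def write_volume(array: np.ndarray, grid: VoxelGrid, path) -> None:
    p = Path(path)
    if p.suffix == ".nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(array.transpose(2, 1, 0)))
        img.SetSpacing(tuple(grid.spacing))
        img.SetOrigin(tuple(grid.origin))
        sitk.WriteImage(img, str(p))
        return
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(p))


def read_mask(path, name: str = "", role: str = "oar") -> StructureMask:
    arr, grid = read_volume(path)
    return StructureMask(grid=grid, occupancy=arr > 0.5, name=name or Path(path).stem, role=role)  # type: ignore[arg-type]


def read_dose(path, prescription: float) -> DoseGrid:
    arr, grid = read_volume(path)
    return DoseGrid(grid=grid, dose=np.clip(arr, 0, None), prescription=prescription)


def write_mask(mask: StructureMask, path) -> None:
    write_volume(mask.occupancy.astype(np.uint8), mask.grid, path)


def write_dose(dose: DoseGrid, path) -> None:
    write_volume(dose.dose, dose.grid, path)


# ---------------------------------------------------------------------------
# DICOM-RT


def read_rtdose(path, prescription: float) -> DoseGrid:
    """Read an RTDOSE file, applying DoseGridScaling.

    The dose cube is returned on an x/y/z grid built from ImagePositionPatient,
    PixelSpacing and the GridFrameOffsetVector (which must be uniform).
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    cube = ds.pixel_array.astype(float) * scaling  # (frames, rows, cols)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if dz.size and not np.allclose(dz, dz[0]):
        raise ValueError("non-uniform GridFrameOffsetVector is unsupported")
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    # reorder (frame z, row y, col x) -> (x, y, z)
    dose = cube.transpose(2, 1, 0)
    grid = VoxelGrid(
        shape=dose.shape,
        spacing=(col_sp, row_sp, float(dz[0]) if dz.size else 1.0),
        origin=origin,
    )
    return DoseGrid(grid=grid, dose=np.clip(dose, 0, None), prescription=prescription)


def read_rtstruct(path, grid: VoxelGrid, names: list[str] | None = None) -> dict[str, StructureMask]:
    """Rasterize RTSTRUCT contours onto ``grid`` by per-slice even-odd
    polygon fill (XOR over the contours intersecting one slice)."""
    import pydicom
    from matplotlib.path import Path as MplPath

    ds = pydicom.dcmread(str(path))
    roi_names = {
        roi.ROINumber: roi.ROIName for roi in ds.StructureSetROISequence
    }
    wanted = set(names) if names else None

    xs = grid.axis_coordinates(0)
    ys = grid.axis_coordinates(1)
    zs = grid.axis_coordinates(2)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    points = np.column_stack([xx.ravel(), yy.ravel()])

    out: dict[str, StructureMask] = {}
    for roi in ds.ROIContourSequence:
        name = roi_names.get(roi.ReferencedROINumber, str(roi.ReferencedROINumber))
        if wanted is not None and name not in wanted:
            continue
        occ = np.zeros(grid.shape, dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            k = int(np.argmin(np.abs(zs - pts[0, 2])))
            if abs(zs[k] - pts[0, 2]) > grid.spacing[2] / 2 + 1e-6:
                logger.warning("contour of %s at z=%.2f outside grid; skipped", name, pts[0, 2])
                continue
            inside = MplPath(pts[:, :2]).contains_points(points).reshape(
                grid.shape[0], grid.shape[1]
            )
            occ[:, :, k] ^= inside  # XOR -> even-odd rule across contours
        out[name] = StructureMask(grid=grid, occupancy=occ, name=name)
    return out
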