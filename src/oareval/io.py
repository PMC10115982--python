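"""Readers and writers for the standard radiotherapy formats.

Readers: DICOM RT Structure Set (planar contours -> masks), DICOM RT Dose
(grid + dose scaling), NIfTI label/mask volumes.  Writers: NIfTI masks and
dose, a JSON structure-set manifest, and the long-format CSV tables.

Only axis-aligned geometries are supported (identity in-plane orientation);
writing DICOM-RT Structure Sets is out of scope.  World coordinates are mm,
dose Gy, volumes cc.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .dosimetry import DoseGrid
from .errors import InvalidGeometryError, UnsupportedOrientationError
from .grid import BinaryMask, Contour, StructureSet, VoxelGrid, rasterize_contours

PathLike = Union[str, os.PathLike]

_AXIAL_ORIENTATION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


# ---------------------------------------------------------------------------
# DICOM


def _check_orientation(iop: Sequence[float], tol: float = 1e-4) -> None:
    if max(abs(a - b) for a, b in zip(iop, _AXIAL_ORIENTATION)) > tol:
        raise UnsupportedOrientationError(
            f"only identity (axial) image orientation is supported, got {list(iop)}"
        )


def read_rtstruct_contours(source) -> Dict[str, List[Contour]]:
    """Read planar contours from an RT Structure Set.

    ``source`` is a path or an open :class:`pydicom.Dataset`.  Returns a
    mapping from ROI name to its list of axial :class:`Contour` polygons; an
    ROI delivered without contour data maps to an empty list.
    """
    import pydicom

    ds = source if hasattr(source, "StructureSetROISequence") else pydicom.dcmread(source)
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    out: Dict[str, List[Contour]] = {name: [] for name in names.values()}
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(roi_contour.ReferencedROINumber))
        if name is None:
            continue
        for item in getattr(roi_contour, "ContourSequence", []):
            data = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            out[name].append(Contour.from_points3d(data))
    return out


def rtstruct_to_structure_set(
    source,
    grid: VoxelGrid,
    case_id: str,
    arm: str,
    expected_names: Optional[Sequence[str]] = None,
) -> StructureSet:
    """Rasterize an RT Structure Set onto a grid.

    Names in ``expected_names`` that the file does not deliver are recorded
    as absent (distinct from delivered-but-empty).
    """
    contours = read_rtstruct_contours(source)
    structures: Dict[str, Optional[BinaryMask]] = {}
    for name, polys in contours.items():
        structures[name] = rasterize_contours(polys, grid)
    for name in expected_names or ():
        structures.setdefault(name, None)
    return StructureSet(case_id, arm, structures)


def read_rtdose(source) -> DoseGrid:
    """Read an RT Dose grid (pixel data x DoseGridScaling, Gy)."""
    import pydicom

    ds = source if hasattr(source, "pixel_array") or hasattr(source, "PixelData") \
        else pydicom.dcmread(source)
    _check_orientation([float(v) for v in ds.ImageOrientationPatient])
    scaling = float(ds.DoseGridScaling)
    arr = ds.pixel_array.astype(float) * scaling  # (frames, rows, cols) = (z, y, x)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if offsets.size > 1 and (np.abs(dz - dz[0]) > 1e-6).any():
        raise InvalidGeometryError("non-uniform dose frame spacing is unsupported")
    spacing_z = float(dz[0]) if offsets.size > 1 else 1.0
    if spacing_z <= 0:
        raise UnsupportedOrientationError("dose frames must advance in +z")
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # (row=y, col=x)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    grid = VoxelGrid(origin, (col_sp, row_sp, spacing_z),
                     (arr.shape[2], arr.shape[1], arr.shape[0]))
    return DoseGrid(grid, np.ascontiguousarray(arr.transpose(2, 1, 0)))


# ---------------------------------------------------------------------------
# NIfTI


def _grid_to_affine(grid: VoxelGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def _affine_to_grid(affine: np.ndarray, shape: Sequence[int]) -> VoxelGrid:
    rot = np.asarray(affine)[:3, :3]
    if np.abs(rot - np.diag(np.diag(rot))).max() > 1e-6:
        raise UnsupportedOrientationError(
            "only diagonal (axis-aligned) NIfTI affines are supported"
        )
    spacing = np.diag(rot)
    if (spacing <= 0).any():
        raise UnsupportedOrientationError("NIfTI affine must have positive diagonal")
    # NIfTI affines are float32; round to nm scale so grids written by this
    # package compare equal after a round trip
    origin = np.round(np.asarray(affine, dtype=float)[:3, 3], 6)
    return VoxelGrid(tuple(origin), tuple(np.round(spacing, 6)), tuple(shape))


def write_nifti_mask(mask: BinaryMask, path: PathLike) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8),
                          _grid_to_affine(mask.grid))
    nib.save(img, os.fspath(path))


def read_nifti_mask(path: PathLike) -> BinaryMask:
    import nibabel as nib

    img = nib.load(os.fspath(path))
    grid = _affine_to_grid(img.affine, img.shape[:3])
    return BinaryMask(grid, np.asarray(img.dataobj) > 0.5)


def write_nifti_dose(dose: DoseGrid, path: PathLike) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(dose.dose.astype(np.float32), _grid_to_affine(dose.grid))
    nib.save(img, os.fspath(path))


def read_nifti_dose(path: PathLike) -> DoseGrid:
    import nibabel as nib

    img = nib.load(os.fspath(path))
    grid = _affine_to_grid(img.affine, img.shape[:3])
    return DoseGrid(grid, np.asarray(img.dataobj, dtype=float))


# ---------------------------------------------------------------------------
# JSON manifest (one structure set on disk as NIfTI masks + index)


def write_structure_set(
    structset: StructureSet, directory: PathLike, stem: Optional[str] = None
) -> Path:
    """Write a structure set as NIfTI masks plus a JSON manifest; returns
    the manifest path.  Absent structures appear in the manifest with a
    null path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{structset.case_id}_{structset.arm}".replace("+", "")
    entries: Dict[str, Optional[str]] = {}
    for name, mask in structset.structures.items():
        if mask is None:
            entries[name] = None
            continue
        fname = f"{stem}_{name}.nii.gz"
        write_nifti_mask(mask, directory / fname)
        entries[name] = fname
    manifest = {
        "case_id": structset.case_id,
        "arm": structset.arm,
        "structures": entries,
    }
    path = directory / f"{stem}.manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_structure_set(manifest_path: PathLike) -> StructureSet:
    """Read a structure set written by :func:`write_structure_set`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    structures: Dict[str, Optional[BinaryMask]] = {}
    for name, fname in manifest["structures"].items():
        structures[name] = (
            None if fname is None else read_nifti_mask(manifest_path.parent / fname)
        )
    return StructureSet(manifest["case_id"], manifest["arm"], structures)
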