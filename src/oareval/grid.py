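"""Voxel-grid geometry substrate.

World-aligned anisotropic voxel grids, binary structure masks, planar
contours, and the raster operations every agreement metric is built on:
contour rasterization (even-odd voxel-center rule), nearest-neighbour
resampling, boundary extraction, volumes, centroids and boolean algebra.

Conventions
-----------
* World coordinates are millimetres.  Grids are axis-aligned; oblique
  acquisitions are out of scope.
* Arrays are indexed ``[i, j, k]`` with ``world = origin + index * spacing``;
  the third axis (``k``) is the slicing (axial) axis, so a typical
  head-and-neck grid has spacing ``(1.27, 1.27, 2.0)`` mm.
* ``origin`` is the world position of the *center* of voxel ``(0, 0, 0)``.
* Volumes are reported in cc (1 cc = 1000 mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import (
    GridMismatchError,
    InvalidGeometryError,
    UndefinedMetricError,
    UnsupportedOrientationError,
)

MM3_PER_CC = 1000.0


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned anisotropic voxel lattice in patient space.

    Parameters
    ----------
    origin : tuple of float
        World coordinates (mm) of the center of voxel ``(0, 0, 0)``.
    spacing : tuple of float
        Per-axis voxel size (mm); strictly positive, anisotropy allowed.
    shape : tuple of int
        Voxel counts per axis; strictly positive.
    """

    origin: Tuple[float, float, float]
    spacing: Tuple[float, float, float]
    shape: Tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise InvalidGeometryError("VoxelGrid is three-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise InvalidGeometryError(f"spacing must be > 0, got {self.spacing}")
        if any(n <= 0 for n in self.shape):
            raise InvalidGeometryError(f"shape must be > 0, got {self.shape}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to world mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) world mm points to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class BinaryMask:
    """Per-voxel boolean occupancy of one structure on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != tuple(self.grid.shape):
            raise InvalidGeometryError(
                f"occupancy shape {occ.shape} != grid shape {self.grid.shape}"
            )
        self.occupancy = occ.astype(bool)

    @classmethod
    def empty(cls, grid: VoxelGrid) -> "BinaryMask":
        return cls(grid, np.zeros(grid.shape, dtype=bool))

    @property
    def foreground_count(self) -> int:
        return int(self.occupancy.sum())

    def is_empty(self) -> bool:
        return not self.occupancy.any()

    def foreground_centers(self) -> np.ndarray:
        """(N, 3) world-mm centers of foreground voxels."""
        idx = np.argwhere(self.occupancy)
        if idx.size == 0:
            return np.empty((0, 3))
        return self.grid.index_to_world(idx)


@dataclass(frozen=True)
class Contour:
    """One closed planar polygon on an axial slice.

    ``vertices`` is an (N, 2) array of in-plane ``(x, y)`` mm coordinates,
    closed implicitly (last vertex connects back to the first);
    ``slice_position`` is the world mm coordinate along the slicing axis.
    """

    slice_position: float
    vertices: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise InvalidGeometryError(
                "a contour needs >= 3 planar (x, y) vertices"
            )
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "slice_position", float(self.slice_position))

    @classmethod
    def from_points3d(cls, points: np.ndarray, tol: float = 1e-3) -> "Contour":
        """Build from (N, 3) world points; the plane must be axial within ``tol`` mm."""
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
            raise InvalidGeometryError("need >= 3 three-dimensional vertices")
        z = pts[:, 2]
        if np.ptp(z) > tol:
            raise UnsupportedOrientationError(
                f"contour plane not axial: z range {np.ptp(z):.4f} mm exceeds {tol} mm"
            )
        return cls(float(z.mean()), pts[:, :2])


# Sentinel marking a structure that was never delivered (distinct from a
# delivered-but-empty mask, which is a BinaryMask with zero foreground).
ABSENT = None


@dataclass
class StructureSet:
    """Named, possibly-absent structures of one case and one arm.

    ``structures`` maps a standardized OAR/target name to a
    :class:`BinaryMask`, or to ``None`` (the :data:`ABSENT` marker) when the
    structure was not delivered.  Absence is distinct from a delivered empty
    mask for presence accounting; for geometry both are unusable and
    :meth:`is_present` treats a zero-foreground delivery as not present.
    All masks in one set share one grid.
    """

    case_id: str
    arm: str
    structures: Dict[str, Optional[BinaryMask]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.structures)
        if len(names) != len(set(names)):
            raise InvalidGeometryError("structure names must be unique in a set")
        grids = {m.grid for m in self.structures.values() if m is not None}
        if len(grids) > 1:
            raise GridMismatchError("all masks in a StructureSet must share one grid")

    @property
    def grid(self) -> Optional[VoxelGrid]:
        for m in self.structures.values():
            if m is not None:
                return m.grid
        return None

    def names(self) -> List[str]:
        return list(self.structures)

    def is_present(self, name: str) -> bool:
        """Delivered with non-empty geometry."""
        m = self.structures.get(name, ABSENT)
        return m is not None and not m.is_empty()

    def get(self, name: str) -> Optional[BinaryMask]:
        return self.structures.get(name, ABSENT)


# ---------------------------------------------------------------------------
# rasterization


def _even_odd_inside(xs: np.ndarray, ys: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon for a lattice of candidate points.

    Half-open scanline semantics: an edge contributes for y in
    [min(y1,y2), max(y1,y2)) and a point counts a crossing when it lies
    strictly left of the edge's x-intercept, so points exactly on a shared
    edge resolve deterministically toward the lower coordinate.
    Returns a (len(xs), len(ys)) boolean array.
    """
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    inside = np.zeros(X.shape, dtype=bool)
    verts = np.asarray(polygon, dtype=float)
    n = verts.shape[0]
    for a in range(n):
        x1, y1 = verts[a]
        x2, y2 = verts[(a + 1) % n]
        if y1 == y2:
            continue
        lo, hi = (y1, y2) if y1 < y2 else (y2, y1)
        band = (Y >= lo) & (Y < hi)
        if not band.any():
            continue
        x_int = x1 + (Y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= band & (X < x_int)
    return inside


def rasterize_contours(contours: Sequence[Contour], grid: VoxelGrid) -> BinaryMask:
    """Rasterize planar axial contours onto a grid.

    A voxel is foreground iff its center lies inside an odd number of the
    polygons on its slice (even-odd rule); contours outside the grid are
    clipped; an empty contour list yields an empty mask.
    """
    occ = np.zeros(grid.shape, dtype=bool)
    xs = grid.axis_centers(0)
    ys = grid.axis_centers(1)
    z0, dz, nz = grid.origin[2], grid.spacing[2], grid.shape[2]
    for contour in contours:
        if not isinstance(contour, Contour):
            contour = Contour(contour[0], contour[1])  # tolerate (z, verts) pairs
        k = (contour.slice_position - z0) / dz
        kr = int(np.rint(k))
        if kr < 0 or kr >= nz or abs(k - kr) > 0.5 + 1e-9:
            continue  # clipped: slice outside the grid
        occ[:, :, kr] ^= _even_odd_inside(xs, ys, contour.vertices)
    return BinaryMask(grid, occ)


# ---------------------------------------------------------------------------
# resampling


def resample_nearest(mask: BinaryMask, target: VoxelGrid) -> BinaryMask:
    """Resample occupancy onto ``target`` by nearest voxel center.

    Output voxels whose centers fall outside the input grid extent (beyond
    half a voxel from the outermost centers) are background.  Equidistant
    ties round half to even (numpy rounding), which is deterministic.
    """
    if mask.grid == target:
        return BinaryMask(target, mask.occupancy.copy())
    src = mask.grid
    idx_axes = []
    valid_axes = []
    for a in range(3):
        centers = target.axis_centers(a)
        frac = (centers - src.origin[a]) / src.spacing[a]
        idx = np.rint(frac).astype(int)
        valid = (frac >= -0.5) & (frac <= src.shape[a] - 0.5)
        idx_axes.append(np.clip(idx, 0, src.shape[a] - 1))
        valid_axes.append(valid)
    out = mask.occupancy[np.ix_(*idx_axes)].copy()
    out &= (
        valid_axes[0][:, None, None]
        & valid_axes[1][None, :, None]
        & valid_axes[2][None, None, :]
    )
    return BinaryMask(target, out)


# ---------------------------------------------------------------------------
# boundary extraction


@dataclass
class Boundary:
    """Raster boundary of a mask.

    ``face_centroids``/``face_areas``: centroids (mm) and areas (mm^2) of the
    faces separating a foreground voxel from background or from the grid
    edge.  ``voxel_centers``: world centers (mm) of foreground voxels with at
    least one 6-neighbour background (or grid-edge) face.
    """

    face_centroids: np.ndarray  # (F, 3) mm
    face_areas: np.ndarray  # (F,) mm^2
    voxel_centers: np.ndarray  # (V, 3) mm

    @property
    def total_area_mm2(self) -> float:
        return float(self.face_areas.sum())

    def is_empty(self) -> bool:
        return self.face_centroids.shape[0] == 0


def extract_boundary(mask: BinaryMask) -> Boundary:
    """Extract boundary faces and boundary voxel centers of a mask."""
    grid = mask.grid
    occ = mask.occupancy
    centroids: List[np.ndarray] = []
    areas: List[np.ndarray] = []
    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    for axis in range(3):
        pad = [(0, 0)] * 3
        pad[axis] = (1, 1)
        ext = np.pad(occ, pad, constant_values=False)
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[axis] = slice(1, None)
        sl_lo[axis] = slice(None, -1)
        faces = ext[tuple(sl_hi)] != ext[tuple(sl_lo)]
        idx = np.argwhere(faces).astype(float)  # axis coord m -> plane at m - 0.5
        if idx.size == 0:
            continue
        coords = idx.copy()
        coords[:, axis] -= 0.5
        centroids.append(coords * spacing + origin)
        other = [a for a in range(3) if a != axis]
        areas.append(
            np.full(idx.shape[0], spacing[other[0]] * spacing[other[1]])
        )
    if centroids:
        face_centroids = np.concatenate(centroids, axis=0)
        face_areas = np.concatenate(areas, axis=0)
    else:
        face_centroids = np.empty((0, 3))
        face_areas = np.empty((0,))
    if occ.any():
        interior = ndimage.binary_erosion(
            occ, structure=ndimage.generate_binary_structure(3, 1), border_value=0
        )
        bvox = occ & ~interior
        voxel_centers = grid.index_to_world(np.argwhere(bvox))
    else:
        voxel_centers = np.empty((0, 3))
    return Boundary(face_centroids, face_areas, voxel_centers)


# ---------------------------------------------------------------------------
# mask measurements and algebra


def mask_volume_cc(mask: BinaryMask) -> float:
    """Foreground volume in cc (voxel count x voxel volume)."""
    return mask.foreground_count * (mask.grid.voxel_volume_mm3 / MM3_PER_CC)


def mask_centroid(mask: BinaryMask) -> np.ndarray:
    """Unweighted mean of foreground voxel centers, world mm."""
    if mask.is_empty():
        raise UndefinedMetricError("centroid of an empty mask is undefined")
    return mask.foreground_centers().mean(axis=0)


def mask_boolean(a: BinaryMask, b: BinaryMask, op: str) -> BinaryMask:
    """Voxel-wise boolean combination; masks must share one grid."""
    if a.grid != b.grid:
        raise GridMismatchError("boolean operands must share one grid")
    if op == "union":
        occ = a.occupancy | b.occupancy
    elif op == "intersect":
        occ = a.occupancy & b.occupancy
    elif op == "subtract":
        occ = a.occupancy & ~b.occupancy
    else:
        raise ValueError(f"unknown boolean op {op!r}")
    return BinaryMask(a.grid, occ)


def translate_mask_voxels(mask: BinaryMask, shift_voxels: Sequence[int]) -> BinaryMask:
    """Shift occupancy by an integer number of voxels (zero fill)."""
    occ = mask.occupancy
    out = np.zeros_like(occ)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for a, s in enumerate(int(v) for v in shift_voxels):
        n = occ.shape[a]
        if abs(s) >= n:
            return BinaryMask(mask.grid, out)
        if s >= 0:
            dst[a] = slice(s, n)
            src[a] = slice(0, n - s)
        else:
            dst[a] = slice(0, n + s)
            src[a] = slice(-s, n)
    out[tuple(dst)] = occ[tuple(src)]
    return BinaryMask(mask.grid, out)
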