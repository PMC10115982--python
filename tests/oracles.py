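"""Independent brute-force oracles for the metric implementations.

Everything here is deliberately naive — per-point loops and all-pairs
distance matrices — and shares no code path with the package's KD-tree /
vectorized implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def pnpoly(x: float, y: float, poly: np.ndarray) -> bool:
    """Classic even-odd crossing-count point-in-polygon test (per point)."""
    inside = False
    n = len(poly)
    j = n - 1
    for i in range(n):
        xi, yi = poly[i]
        xj, yj = poly[j]
        if (yi > y) != (yj > y) and x < (xj - xi) * (y - yi) / (yj - yi) + xi:
            inside = not inside
        j = i
    return inside


def brute_rasterize_slice(xs, ys, polygons) -> np.ndarray:
    """Even-odd rasterization of one slice by per-voxel-center loops."""
    out = np.zeros((len(xs), len(ys)), dtype=bool)
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            crossings = sum(pnpoly(x, y, np.asarray(p)) for p in polygons)
            out[i, j] = crossings % 2 == 1
    return out


def brute_boundary_voxels(occ: np.ndarray) -> np.ndarray:
    """Foreground voxels with a 6-neighbour background (or edge) face."""
    nx, ny, nz = occ.shape
    out = np.zeros_like(occ)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not occ[i, j, k]:
                    continue
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                                   (0, 0, 1), (0, 0, -1)):
                    a, b, c = i + di, j + dj, k + dk
                    if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) \
                            or not occ[a, b, c]:
                        out[i, j, k] = True
                        break
    return out


def _min_dists(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    return cdist(points_a, points_b).min(axis=1)


def brute_surface_dice(boundary_a, boundary_b, tau: float) -> float:
    """All-pairs area-weighted surface Dice from two Boundary objects."""
    da = _min_dists(boundary_a.face_centroids, boundary_b.face_centroids)
    db = _min_dists(boundary_b.face_centroids, boundary_a.face_centroids)
    num = boundary_a.face_areas[da <= tau].sum() + boundary_b.face_areas[db <= tau].sum()
    return float(num / (boundary_a.face_areas.sum() + boundary_b.face_areas.sum()))


def brute_hd95(points_a: np.ndarray, points_b: np.ndarray) -> float:
    d_ab = np.percentile(_min_dists(points_a, points_b), 95, method="linear")
    d_ba = np.percentile(_min_dists(points_b, points_a), 95, method="linear")
    return float(max(d_ab, d_ba))


def brute_apl(ref_slice_boundary_points, cand_surface_points, tol, pitch) -> float:
    if len(ref_slice_boundary_points) == 0:
        return 0.0
    if len(cand_surface_points) == 0:
        return float(len(ref_slice_boundary_points)) * pitch
    d = _min_dists(ref_slice_boundary_points, cand_surface_points)
    return float((d > tol).sum()) * pitch


def brute_cdc(points_a: np.ndarray, points_b: np.ndarray, tol: float) -> float:
    na = int((_min_dists(points_a, points_b) <= tol).sum())
    nb = int((_min_dists(points_b, points_a) <= tol).sum())
    return (na + nb) / (len(points_a) + len(points_b))


def brute_dilate(occ: np.ndarray, spacing, margin_mm: float) -> np.ndarray:
    """Voxel centers within margin of any foreground voxel center (all pairs)."""
    spacing = np.asarray(spacing, dtype=float)
    fg = np.argwhere(occ) * spacing
    if fg.size == 0:
        return np.zeros_like(occ)
    allpts = np.argwhere(np.ones_like(occ)) * spacing
    d = cdist(allpts, fg).min(axis=1)
    return (d <= margin_mm).reshape(occ.shape)


def random_blob(rng: np.random.Generator, shape, spacing=(1.0, 1.0, 1.0),
                threshold: float = 0.75):
    """Random smooth blob mask; may be empty for high thresholds."""
    from scipy import ndimage

    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=2.0)
    smooth = (smooth - smooth.mean()) / (smooth.std() + 1e-12)
    return smooth > threshold


def lens_volume(r: float, d: float) -> float:
    """Intersection volume of two equal spheres of radius r, centers d apart."""
    return np.pi / 12.0 * (4.0 * r + d) * (2.0 * r - d) ** 2
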