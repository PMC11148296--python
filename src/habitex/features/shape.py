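"""3D shape features of a binary mask in physical coordinates.

Volume, surface area, and sphericity come from a marching-cubes surface
mesh of the (zero-padded) mask.  Maximum diameters are computed over the
corner vertices of the boundary voxels' cubes — this stays exact for
degenerate masks (a single voxel yields the 8 cube corners, so the 3D
diameter is the cube diagonal) where a marching-cubes mesh would collapse.
Axis lengths come from a PCA of the voxel-center coordinates.

Axis/plane convention (arrays ordered z, y, x):

* Maximum2DDiameterSlice  — axial plane, drops z
* Maximum2DDiameterColumn — coronal plane, drops y (anterior-posterior)
* Maximum2DDiameterRow    — sagittal plane, drops x
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

__all__ = ["shape_features", "SHAPE_FEATURE_NAMES"]

SHAPE_FEATURE_NAMES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance; convex hull first when it helps."""
    pts = np.unique(points, axis=0)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 50:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (flat) point set; brute force below
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _boundary_corner_points(mask: np.ndarray, spacing) -> np.ndarray:
    boundary = mask & ~ndimage.binary_erosion(mask)
    centers = np.argwhere(boundary).astype(np.float64)
    offsets = np.array(np.meshgrid([-0.5, 0.5], [-0.5, 0.5], [-0.5, 0.5],
                                   indexing="ij")).reshape(3, -1).T
    corners = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    return corners * np.asarray(spacing, dtype=np.float64)


def _mesh(mask: np.ndarray, spacing):
    # light smoothing before meshing suppresses the staircase facets that
    # would otherwise inflate the surface area of rasterized shapes
    padded = np.pad(mask.astype(np.float64), 2)
    smoothed = ndimage.gaussian_filter(padded, sigma=0.8)
    if smoothed.max() <= 0.5:  # tiny structures smooth away; mesh raw
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5,
                                                spacing=tuple(spacing))
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v = verts - verts.mean(axis=0)
    a, b, c = v[faces[:, 0]], v[faces[:, 1]], v[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0))


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    """Compute the 14-feature 3D shape set; all values finite, never NaN."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = float(np.prod(spacing))

    verts, faces = _mesh(mask, spacing)
    mesh_volume = _mesh_volume(verts, faces)
    surface_area = float(measure.mesh_surface_area(verts, faces))
    # guard degenerate meshes (sub-voxel structures)
    mesh_volume = max(mesh_volume, 1e-12)
    surface_area = max(surface_area, 1e-12)

    corners = _boundary_corner_points(mask, spacing)
    max3d = _max_pairwise(corners)
    diam = {}
    for name, drop_axis in (("Maximum2DDiameterSlice", 0),
                            ("Maximum2DDiameterColumn", 1),
                            ("Maximum2DDiameterRow", 2)):
        keep = [a for a in range(3) if a != drop_axis]
        diam[name] = _max_pairwise(corners[:, keep])

    centers = np.argwhere(mask).astype(np.float64) * np.asarray(spacing)
    if len(centers) > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(centers.T)))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)
    if eig[0] > 0:
        elongation = float(np.sqrt(eig[1] / eig[0]))
        flatness = float(np.sqrt(eig[2] / eig[0]))
    else:  # single voxel: perfectly isotropic by convention
        elongation = flatness = 1.0

    sphericity = float((36.0 * np.pi * mesh_volume ** 2) ** (1.0 / 3.0)
                       / surface_area)
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": float(mask.sum()) * voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": sphericity,
        "Maximum3DDiameter": max3d,
        **diam,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": elongation,
        "Flatness": flatness,
    }
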