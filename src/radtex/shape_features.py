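"""Mesh- and eigenvalue-based shape descriptors of a 3D region of interest.

The ROI surface is triangulated with marching cubes at the 0.5 isolevel (the
mask is zero-padded by one voxel so the mesh is always closed). Volume is the
sum of signed tetrahedron volumes O_x . (O_y x O_z) / 6 over faces; area is
the sum of half cross-product magnitudes. Axis lengths derive from the
eigenvalues of the covariance of in-mask voxel physical coordinates:
axis length = 4 sqrt(gamma), elongation = sqrt(gamma_minor / gamma_major),
flatness = sqrt(gamma_least / gamma_major).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure

from .volume_io import ROIMask

__all__ = [
    "SurfaceMesh",
    "build_mesh",
    "mesh_volume",
    "surface_area",
    "diameters",
    "axis_features",
    "shape_features",
]


@dataclass
class SurfaceMesh:
    """Triangulated isosurface in physical (mm) coordinates."""

    vertices: np.ndarray  # (n_v, 3) float
    faces: np.ndarray  # (n_f, 3) int vertex indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face references out-of-range vertex index")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_closed(self) -> bool:
        """True if every undirected edge is shared by exactly two faces."""
        edges = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool((counts == 2).all())


def build_mesh(
    mask: ROIMask, spacing: tuple[float, float, float], smoothing_sigma: float = 0.5
) -> SurfaceMesh:
    """Marching-cubes isosurface of the mask at level 0.5, in mm coordinates.

    The binary indicator is lightly Gaussian-smoothed (default sigma 0.5
    voxels) before isosurfacing: a raw binary staircase overestimates the
    surface area of smooth objects by ~9%, which smoothing brings within a
    few percent without biasing the enclosed volume. If smoothing flattens
    the field past the isolevel (tiny ROIs), the raw mask is used instead.
    """
    if not mask.data.any():
        raise ValueError("empty ROI")
    padded = np.pad(mask.data.astype(np.float64), 1)
    surf = padded
    if smoothing_sigma > 0:
        smoothed = ndimage.gaussian_filter(padded, smoothing_sigma)
        if smoothed.max() > 0.5 and smoothed.min() < 0.5:
            surf = smoothed
    verts, faces, _, _ = measure.marching_cubes(surf, level=0.5, spacing=spacing)
    verts = verts - np.asarray(spacing)  # undo the one-voxel pad
    return SurfaceMesh(vertices=verts, faces=faces)


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume as |sum of signed tetrahedron volumes| over faces."""
    if not mesh.is_closed():
        warnings.warn("mesh is not closed; volume is best-effort", stacklevel=2)
    a = mesh.vertices[mesh.faces[:, 0]]
    b = mesh.vertices[mesh.faces[:, 1]]
    c = mesh.vertices[mesh.faces[:, 2]]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    return float(abs(signed.sum()))


def surface_area(mesh: SurfaceMesh) -> float:
    """Sum over faces of half the cross-product magnitude of two edges."""
    a = mesh.vertices[mesh.faces[:, 0]]
    b = mesh.vertices[mesh.faces[:, 1]]
    c = mesh.vertices[mesh.faces[:, 2]]
    return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())


def _max_pairwise(points: np.ndarray) -> float:
    """Max Euclidean pairwise distance; hull-reduced when many points."""
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) > 50:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (flat) point sets fall back to brute force
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def diameters(mesh: SurfaceMesh) -> tuple[float, float]:
    """(max 3D diameter, max 2D axial diameter) over mesh vertices.

    The axial variant projects vertices onto the in-plane axes (0, 1),
    dropping the slice axis.
    """
    if len(mesh.vertices) < 2:
        raise ValueError("diameter needs at least 2 vertices")
    d3 = _max_pairwise(mesh.vertices)
    d2 = _max_pairwise(mesh.vertices[:, :2])
    return d3, d2


def axis_features(
    mask: ROIMask, spacing: tuple[float, float, float]
) -> dict[str, float]:
    """Principal axis lengths, elongation and flatness from voxel coordinates."""
    coords = np.argwhere(mask.data).astype(np.float64) * np.asarray(spacing)
    if len(coords) < 2:
        raise ValueError("axis features need at least 2 voxels")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)  # population covariance
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    g_major, g_minor, g_least = eig
    if g_least == 0.0:
        warnings.warn("degenerate (coplanar/collinear) mask: least axis is 0", stacklevel=2)
    major, minor, least = (4.0 * np.sqrt(g) for g in (g_major, g_minor, g_least))
    elongation = float(np.sqrt(g_minor / g_major)) if g_major > 0 else 0.0
    flatness = float(np.sqrt(g_least / g_major)) if g_major > 0 else 0.0
    return {
        "major_axis_length": float(major),
        "minor_axis_length": float(minor),
        "least_axis_length": float(least),
        "elongation": elongation,
        "flatness": flatness,
    }


def shape_features(mask: ROIMask, spacing: tuple[float, float, float]) -> dict[str, float]:
    """All shape descriptors, keys prefixed ``shape_``."""
    mesh = build_mesh(mask, spacing)
    vm = mesh_volume(mesh)
    am = surface_area(mesh)
    d3, d2 = diameters(mesh)
    feats = {
        "shape_mesh_volume": vm,
        "shape_voxel_volume": mask.n_voxels * float(np.prod(spacing)),
        "shape_surface_area": am,
        "shape_surface_to_volume_ratio": am / vm if vm > 0 else 0.0,
        "shape_max_3d_diameter": d3,
        "shape_max_2d_diameter_axial": d2,
    }
    feats.update({f"shape_{k}": v for k, v in axis_features(mask, spacing).items()})
    return feats
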