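"""Threshold-window hematoma segmentation and surface meshing.

Acute intracerebral blood attenuates at roughly 60-80 HU, between brain
parenchyma (~30 HU) and bone (>300 HU), so an inclusive HU window followed
by largest-connected-region selection isolates the main bleed.  The mask
is turned into (a) a world-coordinate point cloud for the centroid/axis
math and (b) an isosurface mesh, de-voxelized by Laplacian smoothing, for
skull/boundary geometry and visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .volume_io import CTVolume, HematomaMask

__all__ = [
    "ThresholdWindow",
    "LesionPointCloud",
    "SurfaceMesh",
    "threshold_segment",
    "largest_connected_region",
    "morphological_cleanup",
    "mask_to_point_cloud",
    "mask_to_mesh",
    "mask_volume_mm3",
]

BONE_HU_THRESHOLD = 300.0


@dataclass(frozen=True)
class ThresholdWindow:
    """Inclusive HU window; defaults to the acute-blood range 60-80 HU."""

    low: float = 60.0
    high: float = 80.0

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"threshold window requires low < high, got [{self.low}, {self.high}]")


@dataclass(frozen=True)
class LesionPointCloud:
    """World-coordinate (mm) points of lesion voxels, one per voxel centre."""

    points: np.ndarray  # N x 3 mm
    voxel_indices: np.ndarray  # N x 3 int
    spacing: tuple[float, float, float]

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 1:
            raise ValueError("point cloud must be a non-empty N x 3 array")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "voxel_indices", np.asarray(self.voxel_indices, dtype=int))

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangle mesh in world mm."""

    vertices: np.ndarray  # V x 3
    faces: np.ndarray  # F x 3 vertex indices
    watertight: bool = False

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(
            vertices=np.asarray(mesh.vertices, dtype=float),
            faces=np.asarray(mesh.faces, dtype=int),
            watertight=bool(mesh.is_watertight),
        )

    def export(self, path) -> None:
        """Write STL or PLY depending on the file extension."""
        self.to_trimesh().export(str(path))


def threshold_segment(vol: CTVolume, window: ThresholdWindow = ThresholdWindow()) -> HematomaMask:
    """Mask of voxels with ``low <= HU <= high`` (both bounds inclusive)."""
    mask = (vol.data >= window.low) & (vol.data <= window.high)
    return HematomaMask(mask=mask, spacing=vol.spacing, origin=vol.origin)


def _structure(connectivity: int) -> np.ndarray:
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}") from None
    return ndimage.generate_binary_structure(3, order)


def largest_connected_region(mask: HematomaMask, connectivity: int = 26) -> HematomaMask:
    """Keep the connected component with the most voxels.

    Ties are broken deterministically: among equally large components the
    one containing the smallest linear voxel index wins.
    """
    if mask.voxel_count == 0:
        raise ValueError("no hematoma voxels in threshold window")
    labels, n = ndimage.label(mask.mask, structure=_structure(connectivity))
    counts = np.bincount(labels.ravel())[1:]  # skip background
    best = counts.max()
    candidates = np.flatnonzero(counts == best) + 1
    if len(candidates) == 1:
        winner = candidates[0]
    else:
        flat = labels.ravel()
        winner = min(candidates, key=lambda lab: int(np.argmax(flat == lab)))
    return HematomaMask(mask=labels == winner, spacing=mask.spacing, origin=mask.origin)


def _ball_footprint(radius_mm: float, spacing) -> np.ndarray:
    """Ellipsoidal structuring element realising a physical-radius ball."""
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    grids = np.meshgrid(*[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij")
    return sum(g**2 for g in grids) <= radius_mm**2 + 1e-12


def morphological_cleanup(
    mask: HematomaMask, opening_radius_mm: float = 0.0, fill_holes: bool = False
) -> HematomaMask:
    """Binary opening with a physical-radius ball, then optional hole fill.

    ``opening_radius_mm = 0`` with ``fill_holes=False`` is the identity.
    """
    if opening_radius_mm < 0:
        raise ValueError("opening radius must be >= 0")
    out = mask.mask
    if opening_radius_mm > 0:
        footprint = _ball_footprint(opening_radius_mm, mask.spacing)
        if footprint.sum() > 1:
            out = ndimage.binary_opening(out, structure=footprint)
    if fill_holes:
        out = ndimage.binary_fill_holes(out)
    return HematomaMask(mask=out, spacing=mask.spacing, origin=mask.origin)


def mask_to_point_cloud(mask: HematomaMask, vol: CTVolume | None = None) -> LesionPointCloud:
    """One world-coordinate point per true voxel, at the voxel centre."""
    if mask.voxel_count == 0:
        raise ValueError("cannot build a point cloud from an empty mask")
    idx = np.argwhere(mask.mask)
    pts = np.asarray(mask.origin) + idx * np.asarray(mask.spacing)
    return LesionPointCloud(points=pts, voxel_indices=idx, spacing=mask.spacing)


def laplacian_smooth(
    vertices: np.ndarray, faces: np.ndarray, iterations: int = 20, lam: float = 0.5
) -> np.ndarray:
    """Uniform Laplacian relaxation ``v <- v + lam * (mean(neighbours) - v)``.

    Connectivity (and hence topology) is untouched; only vertex positions
    move.  ``iterations=0`` returns the input unchanged.
    """
    verts = np.asarray(vertices, dtype=float).copy()
    if iterations == 0:
        return verts
    from scipy.sparse import coo_matrix

    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    n = len(verts)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    for _ in range(iterations):
        verts += lam * (adj @ verts / deg[:, None] - verts)
    return verts


def mask_to_mesh(
    mask: HematomaMask,
    vol: CTVolume | None = None,
    smoothing_iterations: int = 20,
    smoothing_lambda: float = 0.5,
) -> SurfaceMesh:
    """Marching-cubes isosurface of the binary mask at level 0.5, then
    Laplacian smoothing.  Vertex and face counts are unchanged by the
    smoothing step."""
    if mask.voxel_count == 0:
        raise ValueError("cannot mesh an empty mask")
    padded = np.pad(mask.mask.astype(np.float32), 1)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    except (ValueError, RuntimeError) as exc:
        raise ValueError(f"mask too small to mesh: {exc}") from exc
    verts = verts + np.asarray(mask.origin) - np.asarray(mask.spacing)  # undo the 1-voxel pad
    verts = laplacian_smooth(verts, faces, iterations=smoothing_iterations, lam=smoothing_lambda)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return SurfaceMesh.from_trimesh(mesh)


def skull_mesh(vol: CTVolume, bone_hu: float = BONE_HU_THRESHOLD, smoothing_iterations: int = 10) -> SurfaceMesh:
    """Mesh of the bone compartment (HU >= ``bone_hu``); for a skull shell
    this contains two nested closed surfaces (outer table and inner table)."""
    bone = HematomaMask(mask=vol.data >= bone_hu, spacing=vol.spacing, origin=vol.origin)
    if bone.voxel_count == 0:
        raise ValueError("no bone voxels found for skull meshing")
    return mask_to_mesh(bone, smoothing_iterations=smoothing_iterations)


def mask_volume_mm3(mask: HematomaMask) -> float:
    """Segmented volume in mm^3 (voxel count x voxel volume)."""
    return mask.volume_mm3
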