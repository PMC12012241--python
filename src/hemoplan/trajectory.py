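"""Skull-quadrant reference directions and construction of the L2 path.

The cranium is partitioned into octants about a brain-centred frame.  Four
reference directions point from the frame origin toward the upper-octant
centres: (±1, ±1, 1)/sqrt(3).  These encode the approach angles surgeons
conventionally use (entering through the upper cranium, never the skull
base), so an automated path is steered toward one of them.

The optimized L2 path blends the quadrant reference with the lesion's own
longest axis: its direction Vr bisects the angle between the two (the axis
first oriented into the reference's half-space), its target is the
midpoint between the centroid and the point where the bisector line,
traced from the centroid away from the entry side, exits the hematoma —
biasing the tip toward the dependent part of the bleed for more complete
drainage — and its entry lies on the outer skull surface (or at a fixed
stand-off when no skull is supplied).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .axis_analysis import PrincipalAxes, Trajectory, normalize_axis_sign
from .meshmath import closest_point_on_mesh, point_in_mesh, ray_triangle_hits
from .segmentation import SurfaceMesh
from .volume_io import HematomaMask, PlanningFrame, world_to_voxel

__all__ = [
    "QuadrantModel",
    "L2Plan",
    "assign_quadrant",
    "bisector_direction",
    "boundary_intersection",
    "build_l2",
    "closest_skull_entry",
    "build_quadrant_path_upper",
    "outer_skull_surface",
    "ray_surface_exit",
]

# labels follow clinical convention; geometry follows the direction vectors
QUADRANT_TABLE = (
    ("front-upper", (1, 1, 1)),
    ("back-upper", (-1, 1, 1)),
    ("front-lower", (1, -1, 1)),
    ("back-lower", (-1, -1, 1)),
)

BOUNDARY_REFINE_TOL_MM = 0.01


@dataclass(frozen=True)
class QuadrantModel:
    """Brain-centred frame plus the four upper-quadrant reference directions."""

    frame: PlanningFrame

    @property
    def reference_directions(self) -> dict[str, np.ndarray]:
        return {
            label: np.asarray(vec, dtype=float) / np.sqrt(3.0) for label, vec in QUADRANT_TABLE
        }


@dataclass(frozen=True)
class L2Plan:
    quadrant: str
    lower_region: bool
    reference_direction: np.ndarray
    bisector_vr: np.ndarray
    boundary_intersection: np.ndarray
    target: np.ndarray
    entry: np.ndarray
    trajectory: Trajectory

    def to_dict(self) -> dict:
        return {
            "quadrant": self.quadrant,
            "lower_region": bool(self.lower_region),
            "reference_direction": [float(v) for v in self.reference_direction],
            "vr": [float(v) for v in self.bisector_vr],
            "boundary_mm": [float(v) for v in self.boundary_intersection],
            "target_mm": [float(v) for v in self.target],
            "entry_mm": [float(v) for v in self.entry],
            "clipped_to_skull": bool(self.trajectory.clipped_to_skull),
        }


def assign_quadrant(centroid, frame: PlanningFrame) -> tuple[str, np.ndarray, bool]:
    """Quadrant of the centroid and its (world-space) reference direction.

    The quadrant is read off the signs of the centroid's (x, y) frame
    coordinates; coordinates exactly 0 go to the positive side.  A lower
    (z < 0) centroid keeps the matching *upper*-quadrant direction and is
    flagged instead — approaches through the skull base are never planned.
    """
    local = frame.to_frame(centroid)
    sx = 1 if local[0] >= 0 else -1
    sy = 1 if local[1] >= 0 else -1
    for label, vec in QUADRANT_TABLE:
        if vec[0] == sx and vec[1] == sy:
            ref_local = np.asarray(vec, dtype=float) / np.sqrt(3.0)
            ref_world = frame.axes.T @ ref_local
            return label, ref_world, bool(local[2] < 0)
    raise AssertionError("unreachable: quadrant table covers all sign pairs")


def bisector_direction(reference: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Unit bisector Vr of the angle between the quadrant reference and the
    lesion's longest axis.

    The axis is a line, not a ray, so it is first oriented into the
    reference's half-space (``dot(axis, reference) >= 0``; an exactly
    orthogonal pair keeps the superior-oriented sign).  The bisector of two
    unit vectors is then simply their normalised sum, which bisects the
    angle exactly.
    """
    ref = np.asarray(reference, dtype=float)
    ref = ref / np.linalg.norm(ref)
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    d = float(np.dot(ax, ref))
    if d < 0:
        ax = -ax
    elif d == 0:
        ax = normalize_axis_sign(ax)
    s = ref + ax
    norm = np.linalg.norm(s)
    if norm < 1e-12:
        raise ValueError("reference and axis are antiparallel after orientation")
    return s / norm


def _point_in_mask(mask: HematomaMask, world: np.ndarray) -> bool:
    idx = world_to_voxel(mask, world)
    if np.any(idx < 0) or np.any(idx >= np.asarray(mask.shape)):
        return False
    return bool(mask.mask[tuple(idx)])


def boundary_intersection(
    centroid: np.ndarray, vr: np.ndarray, region: HematomaMask | SurfaceMesh
) -> np.ndarray:
    """First exit of the bisector line out of the hematoma.

    The line is traced from the centroid along the advance direction -Vr
    (deeper along the puncture line, away from the entry side).  For a
    voxel mask the crossing is bracketed by marching at half the minimum
    spacing and refined by bisection to 0.01 mm; for a surface mesh the
    exact ray-triangle intersection is used.
    """
    centroid = np.asarray(centroid, dtype=float)
    advance = -np.asarray(vr, dtype=float)
    advance = advance / np.linalg.norm(advance)

    if isinstance(region, SurfaceMesh):
        hit = ray_surface_exit(centroid, advance, region.to_trimesh(), nearest=True)
        if hit is None:
            raise ValueError("bisector line does not intersect the hematoma surface")
        return hit

    if not _point_in_mask(region, centroid):
        raise ValueError("centroid is not inside the hematoma mask")
    step = min(region.spacing) / 2.0
    max_dist = float(np.linalg.norm(np.asarray(region.shape) * np.asarray(region.spacing)))
    t_in = 0.0
    t_out = None
    t = step
    while t <= max_dist:
        if _point_in_mask(region, centroid + t * advance):
            t_in = t
        else:
            t_out = t
            break
        t += step
    if t_out is None:
        raise ValueError("no hematoma boundary found within the volume extent")
    while t_out - t_in > BOUNDARY_REFINE_TOL_MM:
        mid = 0.5 * (t_in + t_out)
        if _point_in_mask(region, centroid + mid * advance):
            t_in = mid
        else:
            t_out = mid
    return centroid + 0.5 * (t_in + t_out) * advance


def build_l2(
    axes: PrincipalAxes,
    quadrant: QuadrantModel,
    mask: HematomaMask,
    skull: SurfaceMesh | None = None,
    entry_distance_mm: float = 125.0,
    lesion_surface: SurfaceMesh | None = None,
) -> L2Plan:
    """Construct the optimized L2 plan.

    ``lesion_surface`` optionally replaces the voxel mask for the boundary
    intersection (sub-voxel accuracy via exact ray-triangle tests).
    """
    label, reference, lower_flag = assign_quadrant(axes.centroid, quadrant.frame)
    vr = bisector_direction(reference, axes.longest_axis)
    region = lesion_surface if lesion_surface is not None else mask
    boundary = boundary_intersection(axes.centroid, vr, region)
    target = 0.5 * (axes.centroid + boundary)

    entry = target + entry_distance_mm * vr
    clipped = False
    if skull is not None:
        exit_point = ray_surface_exit(target, vr, outer_skull_surface(skull))
        if exit_point is not None:
            if float(np.linalg.norm(exit_point - target)) < entry_distance_mm:
                entry = exit_point
                clipped = True
    traj = Trajectory(entry=entry, target=target, label="L2", clipped_to_skull=clipped)
    return L2Plan(
        quadrant=label,
        lower_region=lower_flag,
        reference_direction=reference,
        bisector_vr=vr,
        boundary_intersection=boundary,
        target=target,
        entry=entry,
        trajectory=traj,
    )


def outer_skull_surface(skull: SurfaceMesh | trimesh.Trimesh) -> trimesh.Trimesh:
    """Outer table of a skull-shell mesh.

    A closed shell meshes into two nested surfaces; the outer one is the
    connected component with the largest bounding box.
    """
    mesh = skull.to_trimesh() if isinstance(skull, SurfaceMesh) else skull
    parts = mesh.split(only_watertight=False)
    if len(parts) <= 1:
        return mesh
    extents = [np.prod(p.bounding_box.extents) for p in parts]
    return parts[int(np.argmax(extents))]


def ray_surface_exit(
    origin: np.ndarray, direction: np.ndarray, mesh: trimesh.Trimesh, nearest: bool = False
) -> np.ndarray | None:
    """Intersection of the ray ``origin + t*direction`` (t > 0) with a mesh.

    Returns the farthest hit (the exit point for an origin inside a closed
    surface), or the nearest hit when ``nearest`` is set; None if the ray
    misses."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    t = ray_triangle_hits(origin, direction, np.asarray(mesh.vertices), np.asarray(mesh.faces))
    if len(t) == 0:
        return None
    return origin + (t[0] if nearest else t[-1]) * direction


def closest_skull_entry(point: np.ndarray, skull: SurfaceMesh) -> np.ndarray:
    """Point on the outer skull surface closest to an interior query point."""
    outer = outer_skull_surface(skull)
    verts = np.asarray(outer.vertices)
    faces = np.asarray(outer.faces)
    point = np.asarray(point, dtype=float)
    if not point_in_mesh(point, verts, faces):
        raise ValueError("query point lies outside the skull surface")
    closest, _ = closest_point_on_mesh(point, verts, faces)
    return closest


def build_quadrant_path_upper(
    centroid: np.ndarray, quadrant: QuadrantModel, skull: SurfaceMesh
) -> Trajectory:
    """Upper-region empirical path: parallel to the quadrant reference
    direction, targeting the centroid, entering where the reference ray
    exits the outer skull surface."""
    label, reference, lower_flag = assign_quadrant(centroid, quadrant.frame)
    if lower_flag:
        raise ValueError("centroid is in the lower region (z < 0); use the L2 construction")
    entry = ray_surface_exit(np.asarray(centroid, dtype=float), reference, outer_skull_surface(skull))
    if entry is None:
        raise ValueError("reference ray does not intersect the skull surface (malformed mesh?)")
    return Trajectory(entry=entry, target=np.asarray(centroid, dtype=float), label=label)
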