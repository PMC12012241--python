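"""CT volume and mask I/O in NIfTI, world coordinates and the planning frame.

World coordinates are millimetres.  Array indices are 0-based and map to
world space axis-aligned: ``world = origin + index * spacing``.  The
anatomical convention used throughout the package is

* x = anterior (+) / posterior (-)
* y = left (+) / right (-)
* z = superior (+) / inferior (-)

so the superior hemisphere of the head is z > 0 in the planning frame.
Oblique acquisitions (non-axis-aligned direction matrices) are rejected at
load time rather than silently re-sampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "PlanningFrame",
    "HematomaMask",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "default_planning_frame",
    "voxel_to_world",
    "world_to_voxel",
    "load_trajectory_json",
    "save_trajectory_json",
]

ANATOMICAL_AXES = ("anterior", "left", "superior")


@dataclass(frozen=True)
class CTVolume:
    """A 3D CT scalar grid in Hounsfield units.

    Parameters
    ----------
    data
        3D float array of HU values.
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm, all positive.
    origin
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: tuple[str, str, str] = ANATOMICAL_AXES

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError(f"expected 3D volume, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite HU values")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass(frozen=True)
class PlanningFrame:
    """Brain-centred coordinate frame for quadrant-theory planning.

    ``center`` is the world-space origin of the quadrant partition, by
    default the geometric centre of the CT bounding box.  ``axes`` are three
    orthonormal row vectors (anterior, left, superior) forming a
    right-handed basis.
    """

    center: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        if center.shape != (3,) or axes.shape != (3, 3):
            raise ValueError("center must be a 3-vector and axes a 3x3 matrix")
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise ValueError("planning-frame axes must be orthonormal")
        if not np.allclose(np.cross(axes[0], axes[1]), axes[2], atol=1e-9):
            raise ValueError("planning frame must be right-handed (anterior x left = superior)")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "axes", axes)

    def to_frame(self, world: np.ndarray) -> np.ndarray:
        """World point -> coordinates in this frame."""
        return self.axes @ (np.asarray(world, dtype=float) - self.center)

    def to_world(self, local: np.ndarray) -> np.ndarray:
        return self.center + self.axes.T @ np.asarray(local, dtype=float)


@dataclass(frozen=True)
class HematomaMask:
    """Binary labelling of hematoma voxels on a CT grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"expected 3D mask, got shape {mask.shape}")
        object.__setattr__(self, "mask", mask.astype(bool))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return self.voxel_count * sx * sy * sz


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _check_axis_aligned(affine: np.ndarray) -> tuple[tuple, tuple]:
    rot = affine[:3, :3]
    spacing = np.sqrt((rot**2).sum(axis=0))
    if np.any(spacing <= 0):
        raise ValueError("NIfTI header has non-positive voxel spacing")
    direction = rot / spacing
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            "oblique (non-axis-aligned) NIfTI direction matrix is not supported; "
            "resample the volume to an axis-aligned grid first"
        )
    return tuple(spacing.tolist()), tuple(affine[:3, 3].tolist())


def load_volume(path) -> CTVolume:
    """Load a 3D NIfTI volume as a :class:`CTVolume`.

    Header scale slope/intercept are applied by nibabel; no further
    rescaling is done, so stored values are interpreted as HU.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected 3D volume, got {len(img.shape)}D image at {path}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    spacing, origin = _check_axis_aligned(img.affine)
    return CTVolume(data=data, spacing=spacing, origin=origin)


def load_mask(path) -> HematomaMask:
    """Load a binary mask (any nonzero voxel counts as hematoma)."""
    vol = load_volume(path)
    return HematomaMask(mask=vol.data > 0.5, spacing=vol.spacing, origin=vol.origin)


def save_volume(vol: CTVolume | HematomaMask, path) -> None:
    """Write a volume or mask to NIfTI.  Masks are stored as uint8."""
    path = Path(path)
    if isinstance(vol, HematomaMask):
        data = vol.mask.astype(np.uint8)
    else:
        data = np.asarray(vol.data)
        if np.allclose(data, np.round(data)) and np.abs(data).max(initial=0) < 2**30:
            data = np.round(data).astype(np.int32)
        else:
            data = data.astype(np.float64)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


save_mask = save_volume


def default_planning_frame(vol: CTVolume, center: np.ndarray | None = None) -> PlanningFrame:
    """Planning frame centred on the image bounding-box centre.

    ``center`` overrides the default, e.g. with a manually located
    ventricular midpoint.
    """
    if center is None:
        half_extent = (np.asarray(vol.shape) - 1) * np.asarray(vol.spacing) / 2.0
        center = np.asarray(vol.origin) + half_extent
    return PlanningFrame(center=np.asarray(center, dtype=float))


def voxel_to_world(vol: CTVolume | HematomaMask, index) -> np.ndarray:
    """World-space centre (mm) of the voxel at ``index``."""
    index = np.asarray(index)
    if np.any(index < 0) or np.any(index >= np.asarray(vol.shape)):
        raise IndexError(f"voxel index {tuple(index)} outside volume shape {vol.shape}")
    return np.asarray(vol.origin) + index * np.asarray(vol.spacing)


def world_to_voxel(vol: CTVolume | HematomaMask, world) -> np.ndarray:
    """Nearest voxel index for a world point (may be out of bounds)."""
    rel = (np.asarray(world, dtype=float) - np.asarray(vol.origin)) / np.asarray(vol.spacing)
    return np.round(rel).astype(int)


def load_trajectory_json(path):
    """Read a trajectory JSON ``{"entry_mm": [...], "target_mm": [...], "label": str}``."""
    from .axis_analysis import Trajectory

    with open(path) as fh:
        obj = json.load(fh)
    return Trajectory(
        entry=np.asarray(obj["entry_mm"], dtype=float),
        target=np.asarray(obj["target_mm"], dtype=float),
        label=obj.get("label", "manual"),
    )


def save_trajectory_json(traj, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "entry_mm": [float(v) for v in traj.entry],
                "target_mm": [float(v) for v in traj.target],
                "label": traj.label,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
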