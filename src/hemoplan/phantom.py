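"""Synthetic head-CT phantoms with known hematoma ground truth.

The phantom emulates the features a threshold-based planner actually sees
in a head CT: an ellipsoidal high-density skull shell (1000 HU), uniform
soft-tissue brain (30 HU), air outside (-1000 HU), and an ellipsoidal
hematoma in the acute-blood window (70 HU by default, inside 60-80 HU so
the standard threshold captures it).  Ground truth (centroid, major axis,
analytic volume, voxel mask) is computed from the generating parameters,
which makes every downstream stage testable without clinical data.

Voxel membership is decided by the voxel *centre* (no antialiasing), so
the ground-truth mask is exactly countable.  Generation is a pure function
of the spec, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .volume_io import CTVolume, HematomaMask

__all__ = ["SkullSpec", "HematomaSpec", "PhantomSpec", "GroundTruth", "make_phantom", "make_multilobe_phantom"]

AIR_HU = -1000.0


@dataclass(frozen=True)
class SkullSpec:
    """Ellipsoidal skull shell: outer semi-axes (mm), shell thickness, HU."""

    outer_semi_axes: tuple[float, float, float] = (62.0, 56.0, 50.0)
    thickness_mm: float = 6.0
    hu: float = 1000.0

    @property
    def inner_semi_axes(self) -> tuple[float, float, float]:
        return tuple(a - self.thickness_mm for a in self.outer_semi_axes)


@dataclass(frozen=True)
class HematomaSpec:
    """Ellipsoidal hematoma: centroid (mm, world), semi-axes a>=b>=c (mm),
    extrinsic-XYZ Euler rotation (deg), mean HU and per-voxel HU jitter sd."""

    centroid_mm: tuple[float, float, float] = (12.0, 8.0, 10.0)
    semi_axes_mm: tuple[float, float, float] = (30.0, 15.0, 10.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hu_mean: float = 70.0
    hu_jitter_sd: float = 0.0

    def __post_init__(self):
        a, b, c = self.semi_axes_mm
        if not (a >= b >= c > 0):
            raise ValueError(f"semi-axes must satisfy a >= b >= c > 0, got {self.semi_axes_mm}")

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True)

    @property
    def major_axis(self) -> np.ndarray:
        """Unit vector of the ellipsoid's longest (a) axis in world space."""
        return self.rotation.apply([1.0, 0.0, 0.0])

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    skull: SkullSpec = field(default_factory=SkullSpec)
    brain_hu: float = 30.0
    hematoma: HematomaSpec = field(default_factory=HematomaSpec)
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def origin(self) -> tuple[float, float, float]:
        # world origin at the grid centre so the planning frame sits at (0,0,0)
        return tuple(-(n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing))


@dataclass(frozen=True)
class GroundTruth:
    mask: HematomaMask
    centroid_mm: np.ndarray
    major_axis: np.ndarray
    volume_mm3: float


def _world_grid(spec: PhantomSpec) -> list[np.ndarray]:
    axes = [
        spec.origin[k] + np.arange(spec.grid_shape[k]) * spec.spacing[k]
        for k in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _inside_ellipsoid(xs, ys, zs, center, semi_axes, rotation: Rotation | None = None):
    """Boolean grid: voxel centre inside the (possibly rotated) ellipsoid."""
    if rotation is None or np.allclose(rotation.as_matrix(), np.eye(3)):
        q = ((xs - center[0]) / semi_axes[0]) ** 2
        q = q + ((ys - center[1]) / semi_axes[1]) ** 2
        q = q + ((zs - center[2]) / semi_axes[2]) ** 2
        return q <= 1.0
    # rotate the offsets into the ellipsoid's own frame
    rt = rotation.as_matrix().T
    dx, dy, dz = xs - center[0], ys - center[1], zs - center[2]
    u = rt[0, 0] * dx + rt[0, 1] * dy + rt[0, 2] * dz
    v = rt[1, 0] * dx + rt[1, 1] * dy + rt[1, 2] * dz
    w = rt[2, 0] * dx + rt[2, 1] * dy + rt[2, 2] * dz
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 + (w / semi_axes[2]) ** 2 <= 1.0


def _check_hematoma_inside_skull(spec: PhantomSpec, hem: HematomaSpec) -> None:
    # sample the hematoma surface densely; every point must lie strictly
    # inside the skull's inner surface
    rng = np.random.default_rng(12345)
    u = rng.normal(size=(2048, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    surf = hem.rotation.apply(u * np.asarray(hem.semi_axes_mm)) + np.asarray(hem.centroid_mm)
    inner = np.asarray(spec.skull.inner_semi_axes)
    if np.any(((surf / inner) ** 2).sum(axis=1) >= 1.0):
        raise ValueError("hematoma ellipsoid is not strictly inside the skull inner surface")


def _check_skull_in_grid(spec: PhantomSpec) -> None:
    half_extent = (np.asarray(spec.grid_shape) - 1) * np.asarray(spec.spacing) / 2.0
    if np.any(np.asarray(spec.skull.outer_semi_axes) >= half_extent):
        raise ValueError("grid too small to contain the skull shell")


def make_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Render the phantom volume and its analytic ground truth.

    Voxels inside the hematoma get ``hu_mean`` plus optional Gaussian
    jitter; skull-shell voxels the skull HU; the remaining intracranial
    voxels the brain HU; exterior voxels -1000 HU.  i.i.d. Gaussian noise
    of sd ``noise_sd`` is then added everywhere.
    """
    _check_skull_in_grid(spec)
    _check_hematoma_inside_skull(spec, spec.hematoma)
    rng = np.random.default_rng(spec.seed)
    xs, ys, zs = _world_grid(spec)
    center = (0.0, 0.0, 0.0)

    outer = _inside_ellipsoid(xs, ys, zs, center, spec.skull.outer_semi_axes)
    inner = _inside_ellipsoid(xs, ys, zs, center, spec.skull.inner_semi_axes)
    hem = _inside_ellipsoid(
        xs, ys, zs, spec.hematoma.centroid_mm, spec.hematoma.semi_axes_mm, spec.hematoma.rotation
    )
    hem &= inner  # guaranteed by the inside-skull check, kept as a hard invariant

    data = np.full(spec.grid_shape, AIR_HU, dtype=np.float64)
    data[outer & ~inner] = spec.skull.hu
    data[inner] = spec.brain_hu
    data[hem] = spec.hematoma.hu_mean
    if spec.hematoma.hu_jitter_sd > 0:
        data[hem] += rng.normal(0.0, spec.hematoma.hu_jitter_sd, size=int(hem.sum()))
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    vol = CTVolume(data=data, spacing=spec.spacing, origin=spec.origin)
    truth = GroundTruth(
        mask=HematomaMask(mask=hem, spacing=spec.spacing, origin=spec.origin),
        centroid_mm=np.asarray(spec.hematoma.centroid_mm, dtype=float),
        major_axis=spec.hematoma.major_axis,
        volume_mm3=spec.hematoma.volume_mm3,
    )
    return vol, truth


def make_multilobe_phantom(
    spec: PhantomSpec,
    second_lobe_offset_mm: tuple[float, float, float],
    second_lobe_semi_axes_mm: tuple[float, float, float],
) -> tuple[CTVolume, GroundTruth]:
    """Two-lobe hematoma: union of the primary ellipsoid and a second one
    at ``centroid + offset``.  Ground-truth centroid/axis are computed
    numerically from the union voxel set (no closed form for a union);
    volume is the union's voxel volume.
    """
    if all(a == 0 for a in second_lobe_semi_axes_mm):
        return make_phantom(spec)

    vol, truth = make_phantom(spec)
    second_center = tuple(
        c + o for c, o in zip(spec.hematoma.centroid_mm, second_lobe_offset_mm)
    )
    axes_sorted = tuple(sorted(second_lobe_semi_axes_mm, reverse=True))
    second = replace(spec.hematoma, centroid_mm=second_center, semi_axes_mm=axes_sorted)
    _check_hematoma_inside_skull(spec, second)

    xs, ys, zs = _world_grid(spec)
    lobe2 = _inside_ellipsoid(xs, ys, zs, second_center, axes_sorted, second.rotation)
    inner = _inside_ellipsoid(xs, ys, zs, (0, 0, 0), spec.skull.inner_semi_axes)
    lobe2 &= inner

    union = truth.mask.mask | lobe2
    data = vol.data.copy()
    rng = np.random.default_rng(spec.seed + 1)
    newly = lobe2 & ~truth.mask.mask
    data[newly] = spec.hematoma.hu_mean
    if spec.hematoma.hu_jitter_sd > 0:
        data[newly] += rng.normal(0.0, spec.hematoma.hu_jitter_sd, size=int(newly.sum()))

    idx = np.argwhere(union)
    pts = np.asarray(spec.origin) + idx * np.asarray(spec.spacing)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    if major[2] < 0:
        major = -major

    mask = HematomaMask(mask=union, spacing=spec.spacing, origin=spec.origin)
    vol2 = CTVolume(data=data, spacing=spec.spacing, origin=spec.origin)
    return vol2, GroundTruth(
        mask=mask, centroid_mm=centroid, major_axis=major, volume_mm3=mask.volume_mm3
    )
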