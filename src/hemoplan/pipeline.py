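"""End-to-end planning pipeline: segment -> axis -> L1/L2 plans.

Every stage's output is written individually next to the combined
``plan.json`` so intermediate results can be inspected or re-used.  With a
fixed configuration the pipeline is fully deterministic: identical inputs
produce bit-identical plan files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import __version__
from .axis_analysis import DEFAULT_ENTRY_DISTANCE_MM, build_l1, longest_axis
from .segmentation import (
    ThresholdWindow,
    largest_connected_region,
    mask_to_point_cloud,
    morphological_cleanup,
    skull_mesh,
    threshold_segment,
)
from .trajectory import QuadrantModel, build_l2
from .volume_io import (
    CTVolume,
    HematomaMask,
    default_planning_frame,
    save_mask,
    save_trajectory_json,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; unknown keys are rejected on load."""

    threshold_low: float = 60.0
    threshold_high: float = 80.0
    connectivity: int = 26
    opening_radius_mm: float = 0.0
    fill_holes: bool = False
    smoothing_iterations: int = 20
    smoothing_lambda: float = 0.5
    entry_distance_mm: float = DEFAULT_ENTRY_DISTANCE_MM
    frame_center: tuple[float, float, float] | None = None
    bone_hu: float = 300.0
    use_skull: bool = True
    seed: int = 0

    def __post_init__(self):
        if not self.threshold_low < self.threshold_high:
            raise ValueError("threshold_low must be < threshold_high")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.opening_radius_mm < 0 or self.entry_distance_mm <= 0:
            raise ValueError("radii/distances out of range")
        if not 0 < self.smoothing_lambda <= 1:
            raise ValueError("smoothing_lambda must be in (0, 1]")

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "frame_center" in obj and obj["frame_center"] is not None:
            obj = {**obj, "frame_center": tuple(obj["frame_center"])}
        return cls(**obj)


def run_pipeline(
    vol: CTVolume,
    config: RunConfig = RunConfig(),
    mask: HematomaMask | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run segmentation (skipped when an external ``mask`` is supplied,
    e.g. from a learned segmenter), axis analysis, and L1/L2 planning.

    Returns the combined plan dictionary; when ``out_dir`` is given the
    stage outputs (mask, axes, L1, L2, plan) are also written there.
    """
    if mask is None:
        window = ThresholdWindow(low=config.threshold_low, high=config.threshold_high)
        mask = threshold_segment(vol, window)
        mask = largest_connected_region(mask, connectivity=config.connectivity)
        if config.opening_radius_mm > 0 or config.fill_holes:
            mask = morphological_cleanup(mask, config.opening_radius_mm, config.fill_holes)
            mask = largest_connected_region(mask, connectivity=config.connectivity)
        segmented = True
    else:
        segmented = False

    cloud = mask_to_point_cloud(mask)
    axes = longest_axis(cloud)

    skull = None
    if config.use_skull and np.any(vol.data >= config.bone_hu):
        skull = skull_mesh(vol, bone_hu=config.bone_hu, smoothing_iterations=config.smoothing_iterations // 2)

    frame = default_planning_frame(vol, center=config.frame_center)
    quadrant = QuadrantModel(frame=frame)

    l1 = build_l1(axes, entry_distance_mm=config.entry_distance_mm, skull=skull)
    l2_plan = build_l2(
        axes, quadrant, mask, skull=skull, entry_distance_mm=config.entry_distance_mm
    )

    plan = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "segmented": segmented,
        "mask_voxel_count": mask.voxel_count,
        "mask_volume_mm3": round(mask.volume_mm3, 6),
        "mask_volume_cm3": round(mask.volume_mm3 / 1000.0, 6),
        "axes": axes.to_dict(),
        "l1": {
            "entry_mm": [float(v) for v in l1.entry],
            "target_mm": [float(v) for v in l1.target],
            "clipped_to_skull": bool(l1.clipped_to_skull),
        },
        "l2": l2_plan.to_dict(),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_mask(mask, out_dir / "mask.nii.gz")
        with open(out_dir / "axes.json", "w") as fh:
            json.dump(axes.to_dict(), fh, indent=2, sort_keys=True)
        save_trajectory_json(l1, out_dir / "l1.json")
        save_trajectory_json(l2_plan.trajectory, out_dir / "l2.json")
        with open(out_dir / "plan.json", "w") as fh:
            json.dump(plan, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return plan
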