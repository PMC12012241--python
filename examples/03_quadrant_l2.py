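"""Quadrant-guided L2 planning.

The centroid's quadrant (signs of its anterior/left coordinates in the
brain-centred frame) selects one of four reference directions
(+-1, +-1, 1)/sqrt(3).  The L2 direction Vr bisects the reference and the
longest axis; the target is the midpoint between the centroid and the
point where the bisector line exits the hematoma on the far side, pulling
the catheter tip toward the dependent part of the bleed.
"""

import numpy as np

from hemoplan import (
    PhantomSpec,
    QuadrantModel,
    build_l2,
    default_planning_frame,
    longest_axis,
    make_phantom,
    mask_to_point_cloud,
    skull_mesh,
)

vol, truth = make_phantom(PhantomSpec())
axes = longest_axis(mask_to_point_cloud(truth.mask))
quadrant = QuadrantModel(frame=default_planning_frame(vol))

plan = build_l2(axes, quadrant, truth.mask, skull=skull_mesh(vol), entry_distance_mm=125.0)
print(f"quadrant            : {plan.quadrant} (lower region: {plan.lower_region})")
print(f"reference direction : {np.round(plan.reference_direction, 4)}")
print(f"bisector Vr         : {np.round(plan.bisector_vr, 4)}")
print(f"boundary point      : {np.round(plan.boundary_intersection, 2)} mm")
print(f"L2 target           : {np.round(plan.target, 2)} mm")
print(f"L2 entry            : {np.round(plan.entry, 2)} mm (on skull: {plan.trajectory.clipped_to_skull})")
depth = np.linalg.norm(plan.target - axes.centroid)
print(f"target depth below centroid along -Vr: {depth:.2f} mm")
# The target sits exactly halfway between centroid and boundary, so the
# depth equals half the centroid-to-boundary distance along -Vr.
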