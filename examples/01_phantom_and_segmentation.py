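"""Generate a synthetic head CT and segment the hematoma.

The phantom embeds a 30x15x10 mm ellipsoidal bleed at 70 HU inside a
1000 HU skull shell.  Thresholding at the acute-blood window (60-80 HU)
followed by largest-connected-region selection should recover the lesion
exactly when no noise is added, and nearly exactly at 5 HU noise after a
1 mm morphological opening.
"""

from hemoplan import (
    PhantomSpec,
    largest_connected_region,
    make_phantom,
    morphological_cleanup,
    threshold_segment,
)

for noise in (0.0, 5.0):
    vol, truth = make_phantom(PhantomSpec(noise_sd=noise, seed=42))
    mask = largest_connected_region(threshold_segment(vol))
    if noise > 0:
        mask = largest_connected_region(
            morphological_cleanup(mask, opening_radius_mm=1.0, fill_holes=True)
        )
    err = 100 * abs(mask.voxel_count - truth.mask.voxel_count) / truth.mask.voxel_count
    print(
        f"noise {noise:3.0f} HU: segmented {mask.voxel_count} voxels "
        f"({mask.volume_mm3 / 1000:.2f} cm^3), truth {truth.mask.voxel_count}, "
        f"volume error {err:.2f}%"
    )
# The error is the fraction of lesion voxels mis-assigned by the threshold
# window; 0% without noise shows the window brackets the lesion exactly.
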