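# hemoplan

Automated puncture-trajectory planning for minimally invasive evacuation
of intracranial hematomas, computed directly from head CT.

Spontaneous intracerebral hemorrhage is often treated by stereotactic
puncture drainage: a catheter is advanced through a small burr hole to a
target inside the hematoma. Choosing the entry point and target is
conventionally a manual, experience-driven step. `hemoplan` implements a
fully computational pipeline for neurosurgical planning research:

1. **Segmentation** — acute blood attenuates at roughly 60–80 HU, between
   brain parenchyma (~30 HU) and bone (>300 HU). An inclusive HU
   threshold window plus largest-connected-region selection isolates the
   main bleed; optional morphological opening and hole-filling clean up
   noise. Masks from external segmenters (e.g. a trained CNN) can be
   plugged in instead.
2. **Axis analysis** — with centred lesion voxel coordinates
   $r_k$, the covariance $C = \frac{1}{N}\sum_k r_k r_k^{\top}$ and the
   unit-mass inertia tensor
   $I = \sum_k \left[(r_k\!\cdot\!r_k)\,\mathrm{Id} - r_k r_k^{\top}\right]$
   share eigenvectors ($I = \mathrm{tr}(S)\,\mathrm{Id} - S$ for the
   scatter $S$). The eigenvector of the *smallest* inertia eigenvalue —
   equivalently the *largest* covariance eigenvalue — is the lesion's
   longest axis. The **L1 path** runs along it into the centroid, with
   the entry at a 10–15 cm stand-off or clipped to the skull surface.
3. **Quadrant-guided planning** — the cranium is partitioned into octants
   about a brain-centred frame; four reference directions
   $(\pm1,\pm1,1)/\sqrt{3}$ encode conventional upper-cranium approach
   angles. The **L2 path** direction $V_r$ bisects the angle between the
   lesion axis and the matching reference direction; its target is the
   midpoint between the centroid and the bisector line's exit through the
   hematoma boundary, biasing the catheter tip toward the dependent part
   of the bleed.
4. **Evaluation** — automated and surgeon-drawn trajectories are compared
   by the angle between their directed entry→target vectors (range
   0–180°), target-to-target distance, and target-to-line distance, with
   per-cohort means, sds and paired t-tests.

A synthetic head-phantom generator (ellipsoidal skull shell, brain tissue,
embedded hematoma with exact analytic ground truth) makes every stage
testable without clinical data.

## Worked example

```sh
python examples/03_quadrant_l2.py
```

```
quadrant            : front-upper (lower region: False)
reference direction : [0.5774 0.5774 0.5774]
bisector Vr         : [0.8881 0.3251 0.3251]
boundary point      : [-7.    1.05  3.05] mm
L2 target           : [2.5  4.52 6.52] mm
L2 entry            : [49.13 21.59 23.59] mm (on skull: True)
target depth below centroid along -Vr: 10.70 mm
```

The lesion centroid at (12, 8, 10) mm lies in the front-upper quadrant,
so the plan blends its longest axis with the (1,1,1)/√3 reference; the
target sits exactly halfway between centroid and the bisector's exit
point through the hematoma boundary, and the entry is the ray's exit
through the outer skull table. `examples/01…04` walk through phantom
segmentation, axis/L1 extraction, L2 planning and trajectory scoring;
`examples/04_compare_trajectories.py` reproduces the published five-case
summary statistics (mean L2 angle 16.36°, mean L1 target distance
16.98 mm, mean L2 target distance 8.97 mm, paired-t p = 0.022).

The same pipeline is scriptable from a shell:

```sh
hemoplan phantom --out-dir work/case0 --seed 3
hemoplan pipeline --vol work/case0/volume.nii.gz --out-dir work/case0/plan
hemoplan compare --manual m.json --l1 work/case0/plan/l1.json --out report.csv
```

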