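# Methods

## Coordinate conventions

World coordinates are millimetres. Array indices are 0-based and map
axis-aligned to world space, `world = origin + index * spacing`; NIfTI
headers with oblique direction matrices are rejected rather than
resampled, because the quadrant geometry is defined in an axis-aligned
anatomical frame. The anatomical convention is x = anterior(+),
y = left(+), z = superior(+), which makes the four quadrant reference
vectors (±1, ±1, 1) point through the upper cranium. The planning frame
defaults to the geometric centre of the CT bounding box; a manually
located ventricular midpoint can be supplied as an override (CLI
`--frame-center`).

## Segmentation

The threshold window is inclusive on both bounds, default [60, 80] HU —
the attenuation range of acute clotted blood. Connected components use
26-connectivity by default (6/18 selectable); among equally large
components the one containing the smallest linear voxel index wins, so
the result is deterministic. Morphological cleanup is a binary opening
with an ellipsoidal structuring element realising a physical-radius ball
(correct under anisotropic spacing), then optional 3-D hole filling.
Volumes are reported in mm³ and cm³; clinical hematoma volumes are of
order tens of cm³, and the voxel-count×voxel-volume estimator is exact
with respect to the mask.

Surface meshes are marching-cubes isosurfaces at the 0.5 level of the
binary mask, followed by uniform Laplacian smoothing
`v ← v + λ(mean(neighbours) − v)` with defaults of 20 iterations and
λ = 0.5 — mild de-voxelization that leaves the vertex/face structure
(and hence topology) untouched. Smoothing affects meshes only: the
centroid/axis math always runs on the raw voxel point cloud, so the
statistical estimates are independent of mesh processing. Shrinkage from
uniform Laplacian smoothing is below 10 % in enclosed volume at these
defaults for lesion-sized bodies; a smoothed lesion surface can
optionally replace the voxel mask in the boundary-intersection step when
sub-voxel accuracy matters.

## Axis analysis

The covariance uses the divide-by-N (population) convention; the divisor
does not affect eigenvectors, hence not the axis. Inertia uses unit
point masses — no HU weighting, since within a thresholded clot HU
variation is noise, not density. Both matrices are diagonalised with a
symmetric eigensolver; the identity `I = tr(S)·Id − S` (scatter S) links
them, so the smallest-inertia eigenvector is exactly the
largest-covariance eigenvector, a property the tests assert to 1e-9.
Axis sign is normalised deterministically (z ≥ 0, ties toward +y then
+x) so repeated runs emit identical plans. Clouds with top-eigenvalue
ratio λ₁/λ₂ < 1.05 get an isotropy flag: for a near-spherical bleed the
"longest axis" is numerically meaningless and the quadrant reference
dominates the plan anyway.

The L1 stand-off defaults to 125 mm, the midpoint of the 10–15 cm
clinical range for needle insertion. On desk-scale phantoms (≤128 mm
grids) the skull is closer than that, so the entry is clipped to the
outer skull table and flagged; smaller stand-offs can be passed to
exercise the fixed-distance rule un-clipped.

## Quadrant model and L2

Quadrant assignment reads the signs of the centroid's (x, y) frame
coordinates; coordinates exactly 0 go to the positive side
(deterministic boundary convention). A lower-region centroid (z < 0)
keeps the matching upper-quadrant reference and raises an advisory flag
instead of modelling skull-base anatomy — no safety-structure atlas is
part of this package. Note the four reference vectors make
arccos(1/√3) ≈ 54.7° with each coordinate axis.

For the bisector, the longest axis (a line, sign-ambiguous) is first
oriented into the reference's half-space (dot ≥ 0; an exactly orthogonal
pair keeps the superior-oriented sign), then `Vr = normalize(ref + axis)`
— the exact angle bisector of two unit vectors. The boundary point is
found by tracing the line from the centroid along −Vr, i.e. away from
the entry side, so the midpoint target sits in the deeper half of the
hematoma and drainage reaches the dependent part of the clot. Against a
voxel mask the crossing is bracketed by marching at half the minimum
spacing and refined by bisection to 0.01 mm (membership is
nearest-voxel, so the located boundary is the voxelized one — within
half a voxel of the continuous surface); against a mesh the exact
ray–triangle intersection is used.

Two entry-point rules exist for quadrant paths: entry along the
reference direction's exit through the skull (`build_quadrant_path_upper`,
the default) and the skull point closest to the centroid
(`closest_skull_entry`). Both are provided; L2 itself enters where Vr
exits the outer skull table, or at the fixed stand-off when no skull
mesh is given. The "outer" table of a skull-shell mesh (which meshes
into two nested closed surfaces) is taken as the connected component
with the largest bounding box.

Mesh queries — ray casting, closest surface point, containment — are
implemented as brute-force vectorised exact tests (Möller–Trumbore;
per-triangle closest-point; ray-parity containment). At the mesh sizes
involved (≲ a few 10⁵ triangles, a handful of queries per plan) this is
fast and has no tolerance knobs.

## Evaluation

Angles use the directed entry→target vectors and live in [0, 180]°; an
undirected convention would fold values above 90° back and could not
represent a plan aimed opposite to the surgeon's. Summary sds use the
n−1 convention; a single case reports sd as null. The paired t-test is
`t = mean(d)/(sd(d)/√n)` with p from Student's t (n−1 df); the test
suite cross-checks p against direct numerical integration of the t
density to 1e-6, so the contract does not depend on any particular CDF
implementation. Degenerate inputs (all differences identical) raise
rather than returning p = NaN. Both readings of "distance to the manual
plan" are computed — target-to-target and target-to-manual-line — with
target-to-target as the headline metric.

## Phantom generator

The phantom emulates exactly the features this planner consumes: an
ellipsoidal skull shell at 1000 HU (outer semi-axes 62×56×50 mm,
6 mm thick — adult-head scale), brain at 30 HU, air at −1000 HU, and an
ellipsoidal hematoma at 70 HU (default semi-axes 30×15×10 mm ≈ 19 cm³,
a large acute bleed; anisotropy λ₁/λ₂ = 4 so the axis is well defined).
Optional per-voxel HU jitter and global Gaussian noise are the only
stochastic elements, driven by a single seed; generation is a pure
function of the spec. Voxel membership is decided by the voxel centre,
making ground truth exactly countable; the analytic centroid, rotated
major axis and (4/3)πabc volume come from the generating parameters. A
two-lobe variant unions a second ellipsoid and derives its ground truth
numerically from the union voxel set.

Deliberately not modelled: CT physics (beam hardening, streaks, partial
volume), ventricles and skull-base anatomy, irregular or multilobed
clinical lesion shapes beyond the two-lobe stress case. Passing phantom
tests therefore demonstrates geometric and statistical correctness of
the pipeline, not robustness to clinical image artefacts — the
segmentation window and the convex-lesion assumptions behind the single
longest axis remain the user's responsibility on real data.

## Problem sizes and determinism

Default phantoms are 128³ voxels at 1 mm (<1 s to generate). Batch
studies (axis recovery over 50 random orientations) use a 96³ grid with
a 27×13×9 mm lesion, large enough that discretization keeps the median
axis error well under 1° while a full batch runs in seconds. All
randomness flows from explicit seeds; plans serialise to JSON with
sorted keys, and re-running the pipeline on identical input and config
yields bit-identical files.

## Known limitations

- The quadrant labels ("front-upper", "back-upper", "front-lower",
  "back-lower") follow the clinical naming of the four upper-octant
  directions; geometry follows the vectors, and the left/right axis is
  not distinguished in the labels.
- Thresholding assumes an acute, homogeneous clot; subacute bleeds drift
  out of the 60–80 HU window.
- For near-isotropic lesions the L1/L2 distinction collapses; the
  isotropy flag should be honoured downstream.
- No vascular or eloquent-cortex avoidance: the quadrant reference
  directions are the only safety prior.
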