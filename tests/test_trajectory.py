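import numpy as np
import pytest

from hemoplan import (
    HematomaMask,
    PlanningFrame,
    QuadrantModel,
    assign_quadrant,
    bisector_direction,
    boundary_intersection,
    build_l2,
    build_quadrant_path_upper,
    closest_skull_entry,
    default_planning_frame,
    longest_axis,
    mask_to_point_cloud,
    skull_mesh,
)
from hemoplan.trajectory import outer_skull_surface, ray_surface_exit

from conftest import ball_mask, make_shell_mesh


def frame0():
    return PlanningFrame(center=np.zeros(3))


def angle_rad(u, v):
    c = float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1, 1)))


class TestAssignQuadrant:
    @pytest.mark.parametrize(
        "centroid,expected_ref,lower",
        [
            ((10, 5, 20), (1, 1, 1), False),
            ((-3, 7, -15), (-1, 1, 1), True),
            ((0, 0, 0), (1, 1, 1), False),  # boundary ties go to the positive side
            ((4, -2, 8), (1, -1, 1), False),
            ((-4, -2, 8), (-1, -1, 1), False),
        ],
    )
    def test_examples(self, centroid, expected_ref, lower):
        label, ref, flag = assign_quadrant(np.array(centroid, float), frame0())
        np.testing.assert_allclose(ref, np.array(expected_ref) / np.sqrt(3))
        assert flag == lower

    def test_sign_flip_equivariance(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            c = rng.uniform(0.5, 30, size=3)
            _, ref, _ = assign_quadrant(c, frame0())
            for flip in ([-1, 1, 1], [1, -1, 1], [-1, -1, 1]):
                _, ref_f, _ = assign_quadrant(c * flip, frame0())
                np.testing.assert_allclose(ref_f[:2], ref[:2] * flip[:2])
                assert ref_f[2] == ref[2]

    def test_reference_directions_superior(self):
        model = QuadrantModel(frame=frame0())
        for ref in model.reference_directions.values():
            assert ref[2] == pytest.approx(1 / np.sqrt(3))


class TestBisector:
    def test_identity(self):
        np.testing.assert_allclose(bisector_direction((0, 0, 1), (0, 0, 1)), (0, 0, 1))

    def test_orthogonal_pair(self):
        vr = bisector_direction((1, 0, 0), (0, 1, 0))
        np.testing.assert_allclose(vr, np.array([1, 1, 0]) / np.sqrt(2))

    def test_axis_reoriented_into_reference_halfspace(self):
        a = bisector_direction((0, 0, 1), (0.3, 0.1, 0.95))
        b = bisector_direction((0, 0, 1), (-0.3, -0.1, -0.95))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_exact_bisection_100_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            ref = rng.normal(size=3)
            ref /= np.linalg.norm(ref)
            ax = rng.normal(size=3)
            ax /= np.linalg.norm(ax)
            vr = bisector_direction(ref, ax)
            if np.dot(ax, ref) < 0:
                ax = -ax
            assert abs(angle_rad(vr, ref) - angle_rad(vr, ax)) < 1e-9


class TestBoundaryIntersection:
    def test_sphere_mesh_radius(self, sphere_mesh_r20):
        rng = np.random.default_rng(12)
        for _ in range(10):
            vr = rng.normal(size=3)
            vr /= np.linalg.norm(vr)
            hit = boundary_intersection(np.zeros(3), vr, sphere_mesh_r20)
            assert np.linalg.norm(hit) == pytest.approx(20.0, abs=0.1)
            # the advance direction is -vr: the hit lies opposite the bisector
            assert np.dot(hit, vr) < 0

    def test_midpoint_target_at_half_radius(self, sphere_mesh_r20):
        vr = np.array([0.0, 0.0, 1.0])
        hit = boundary_intersection(np.zeros(3), vr, sphere_mesh_r20)
        target = 0.5 * (np.zeros(3) + hit)
        assert np.linalg.norm(target) == pytest.approx(10.0, abs=0.05)

    def test_ellipsoid_mask_minor_axis(self):
        # fine 0.25 mm grid: sub-voxel bisection locates the boundary within 0.2 mm
        spacing = 0.25
        n = (256, 136, 104)
        origin = tuple(-(k - 1) * spacing / 2 for k in n)
        ax = [origin[i] + np.arange(n[i]) * spacing for i in range(3)]
        xs, ys, zs = np.meshgrid(*ax, indexing="ij", sparse=True)
        inside = (xs / 30) ** 2 + (ys / 15) ** 2 + (zs / 10) ** 2 <= 1
        mask = HematomaMask(mask=inside, spacing=(spacing,) * 3, origin=origin)
        hit = boundary_intersection(np.zeros(3), np.array([0.0, 0.0, 1.0]), mask)
        assert np.linalg.norm(hit) == pytest.approx(10.0, abs=0.2)

    def test_centroid_outside_mask_raises(self):
        mask = ball_mask(5.0, grid=32)
        with pytest.raises(ValueError, match="inside"):
            boundary_intersection(np.array([20.0, 0, 0]), np.array([0.0, 0, 1]), mask)


class TestBuildL2:
    def test_sphere_geometry(self, default_phantom):
        vol, truth = default_phantom
        axes = longest_axis(mask_to_point_cloud(truth.mask))
        quadrant = QuadrantModel(frame=default_planning_frame(vol))
        plan = build_l2(axes, quadrant, truth.mask, entry_distance_mm=60.0)
        # midpoint definition: target equidistant from centroid and boundary
        d1 = np.linalg.norm(plan.target - axes.centroid)
        d2 = np.linalg.norm(plan.target - plan.boundary_intersection)
        assert d1 == pytest.approx(d2, abs=1e-9)
        # Vr bisects reference and oriented axis exactly
        ax = axes.longest_axis
        if np.dot(ax, plan.reference_direction) < 0:
            ax = -ax
        assert abs(angle_rad(plan.bisector_vr, plan.reference_direction) - angle_rad(plan.bisector_vr, ax)) < 1e-6
        # trajectory advances along -Vr
        np.testing.assert_allclose(plan.trajectory.direction, -plan.bisector_vr, atol=1e-9)

    def test_l2_between_l1_and_reference(self, small_phantom_spec):
        from dataclasses import replace

        from hemoplan import build_l1, make_phantom

        rng = np.random.default_rng(13)
        for _ in range(10):
            spec = replace(
                small_phantom_spec,
                hematoma=replace(
                    small_phantom_spec.hematoma,
                    rotation_deg=tuple(rng.uniform(0, 360, size=3)),
                    centroid_mm=tuple(rng.uniform(-6, 6, size=3)),
                ),
            )
            vol, truth = make_phantom(spec)
            axes = longest_axis(mask_to_point_cloud(truth.mask))
            quadrant = QuadrantModel(frame=default_planning_frame(vol))
            plan = build_l2(axes, quadrant, truth.mask, entry_distance_mm=50.0)
            l1 = build_l1(axes, entry_distance_mm=50.0)
            ax = axes.longest_axis
            if np.dot(ax, plan.reference_direction) < 0:
                ax = -ax
            full = angle_rad(plan.reference_direction, ax)
            assert angle_rad(plan.bisector_vr, ax) <= full + 1e-9
            # Vr lies in the plane spanned by reference and axis
            normal = np.cross(plan.reference_direction, ax)
            if np.linalg.norm(normal) > 1e-9:
                assert abs(np.dot(plan.bisector_vr, normal / np.linalg.norm(normal))) < 1e-9

    def test_skull_clipped_entry(self, default_phantom):
        vol, truth = default_phantom
        skull = skull_mesh(vol)
        axes = longest_axis(mask_to_point_cloud(truth.mask))
        quadrant = QuadrantModel(frame=default_planning_frame(vol))
        plan = build_l2(axes, quadrant, truth.mask, skull=skull, entry_distance_mm=125.0)
        assert plan.trajectory.clipped_to_skull
        assert np.linalg.norm(plan.entry - plan.target) < 125.0
        # entry on the outer skull ellipsoid to mesh/smoothing accuracy
        q = (plan.entry / np.array([62.0, 56.0, 50.0])) ** 2
        assert abs(q.sum() - 1.0) < 0.1


class TestSkullQueries:
    def test_closest_entry_radial_projection(self, shell_mesh):
        p = np.array([20.0, 5.0, -3.0])
        entry = closest_skull_entry(p, shell_mesh)
        expected = p / np.linalg.norm(p) * 60.0
        edge = float(np.mean(outer_skull_surface(shell_mesh).edges_unique_length))
        # faceted sphere: the closest point can slide within one facet
        assert np.linalg.norm(entry - expected) < edge / 2

    def test_closest_entry_matches_brute_force_vertices(self, shell_mesh):
        p = np.array([-10.0, 25.0, 8.0])
        entry = closest_skull_entry(p, shell_mesh)
        outer = outer_skull_surface(shell_mesh)
        verts = np.asarray(outer.vertices)
        brute = verts[np.argmin(np.linalg.norm(verts - p, axis=1))]
        edge = float(np.mean(outer.edges_unique_length))
        assert np.linalg.norm(entry - brute) <= edge

    def test_point_outside_raises(self, shell_mesh):
        with pytest.raises(ValueError, match="outside"):
            closest_skull_entry(np.array([100.0, 0.0, 0.0]), shell_mesh)

    def test_outer_surface_selected(self, shell_mesh):
        outer = outer_skull_surface(shell_mesh)
        radii = np.linalg.norm(np.asarray(outer.vertices), axis=1)
        assert np.all(np.abs(radii - 60.0) < 0.5)


class TestQuadrantPathUpper:
    def test_ray_shell_entry(self):
        shell = make_shell_mesh(outer_r=80.0, inner_r=74.0)
        centroid = np.array([0.0, 0.0, 10.0])
        traj = build_quadrant_path_upper(centroid, QuadrantModel(frame=frame0()), shell)
        np.testing.assert_allclose(traj.target, centroid)
        ref = np.ones(3) / np.sqrt(3)
        # analytic ray-sphere: |c + t*ref| = 80 with |c|=10, c.ref = 10/sqrt(3)
        b = np.dot(centroid, ref)
        t = -b + np.sqrt(b**2 - (np.dot(centroid, centroid) - 80.0**2))
        np.testing.assert_allclose(np.linalg.norm(traj.entry - centroid), t, atol=0.5)
        # direction entry -> target is the reversed reference direction
        np.testing.assert_allclose(traj.direction, -ref, atol=0.01)

    def test_entry_outside_lesion(self, default_phantom):
        vol, truth = default_phantom
        skull = skull_mesh(vol)
        axes = longest_axis(mask_to_point_cloud(truth.mask))
        traj = build_quadrant_path_upper(axes.centroid, QuadrantModel(frame=default_planning_frame(vol)), skull)
        from hemoplan import world_to_voxel

        idx = world_to_voxel(truth.mask, traj.entry)
        in_bounds = np.all(idx >= 0) and np.all(idx < np.array(truth.mask.shape))
        assert not (in_bounds and truth.mask.mask[tuple(idx)])

    def test_lower_centroid_rejected(self):
        shell = make_shell_mesh()
        with pytest.raises(ValueError, match="lower region"):
            build_quadrant_path_upper(np.array([5.0, 5.0, -10.0]), QuadrantModel(frame=frame0()), shell)


def test_ray_surface_exit_misses():
    shell = make_shell_mesh()
    out = ray_surface_exit(np.array([200.0, 0, 0]), np.array([1.0, 0, 0]), outer_skull_surface(shell))
    assert out is None
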