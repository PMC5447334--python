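import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import awplan as aw
from awplan.planning import DegenerateRejectionError, NoAcousticWindowError
from _oracles import (
    brute_force_candidates,
    brute_force_single_view,
    march_segment_hits_hu,
)


def _flat_surface(nx=21, nz=21, pitch=10.0, z0=0.0):
    """Horizontal surface at height z0 with upward normals."""
    xs = pitch * (np.arange(nx) - nx // 2)
    ys = pitch * (np.arange(nz) - nz // 2)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z0)])
    normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    return aw.SurfacePointCloud(pts, normals, np.ones(3))


class TestCandidates:
    def test_depth_constraint_yields_empty_set_error(self, test_probe):
        surf = _flat_surface()
        with pytest.raises(NoAcousticWindowError) as err:
            aw.candidate_surface_points(
                surf, np.array([0.0, 0.0, -150.0]), test_probe, aw.PlannerConfig()
            )
        assert err.value.diagnostics["min_distance_mm"] == pytest.approx(150.0)

    def test_angle_constraint_geometry(self, test_probe):
        surf = _flat_surface()
        target = np.array([0.0, 0.0, -50.0])  # 50 mm below the central point
        cands = aw.candidate_surface_points(surf, target, test_probe, aw.PlannerConfig())
        picked = surf.points[cands.indices]
        centre_in = any(np.allclose(p, [0, 0, 0]) for p in picked)
        lateral_in = any(np.allclose(p, [60, 0, 0], atol=1e-9) for p in picked)
        assert centre_in  # angle 0
        assert not lateral_in  # atan(60/50) ~ 50.2 deg > 30 deg
        # every admitted point individually satisfies both predicates
        assert np.all(cands.distances_mm < test_probe.depth_mm)
        assert np.all(cands.normal_angles_deg <= 30.0 + 1e-9)

    def test_matches_brute_force_on_phantom_surface(self, small_surface, test_probe):
        target = np.array([5.0, 10.0, -8.0])
        cfg = aw.PlannerConfig()
        cands = aw.candidate_surface_points(small_surface, target, test_probe, cfg)
        want = brute_force_candidates(
            small_surface.points, small_surface.normals, target,
            test_probe.depth_mm, cfg.alpha_deg,
        )
        np.testing.assert_array_equal(cands.indices, want)


class TestSingleView:
    def test_homogeneous_tie_breaks_to_lowest_index_and_smallest_roll(self, test_probe):
        vol = aw.CtVolume(
            np.full((50, 50, 50), 40.0, np.float32), np.full(3, 8.0), -np.full(3, 49 * 4.0)
        )
        field = aw.hu_to_mu(vol)
        surf = _flat_surface(nx=5, nz=5, pitch=8.0, z0=80.0)
        cfg = aw.PlannerConfig(angle_step_deg=45.0, ray_step_mm=4.0)
        res = aw.plan_single_view(field, surf, np.array([0.0, 0.0, 0.0]), test_probe, cfg)
        cands = aw.candidate_surface_points(surf, np.zeros(3), test_probe, cfg)
        np.testing.assert_array_equal(res.poses[0].base_point, surf.points[cands.indices[0]])
        assert res.poses[0].phi == 0.0
        assert res.scores[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_joint_argmax(self, small_phantom, small_surface, small_field):
        ct, _, _ = small_phantom
        target = np.array([0.0, 8.0, 0.0])
        geom = aw.ProbeGeometry(n_elements=8, fov_deg=40.0, depth_mm=100.0)
        cfg = aw.PlannerConfig(angle_step_deg=45.0, ray_step_mm=2.0)
        res = aw.plan_single_view(small_field, small_surface, target, geom, cfg)
        cands = aw.candidate_surface_points(small_surface, target, geom, cfg)
        i, j, best = brute_force_single_view(small_field, cands, target, geom, cfg)
        np.testing.assert_array_equal(res.poses[0].base_point, cands.points[i])
        assert res.poses[0].phi == pytest.approx(cfg.roll_grid()[j])
        assert res.scores[0] == pytest.approx(best, abs=1e-12)

    def test_prefers_intercostal_gap(self, small_phantom, small_surface, small_field):
        """With the target at the organ centre the winning pose's central
        scan-line must be rib-free, while some blocked candidate is rated
        strictly lower."""
        ct, _, _ = small_phantom
        target = np.array([0.0, 8.0, 0.0])
        geom = aw.ProbeGeometry(n_elements=5, fov_deg=15.0, depth_mm=90.0)
        cfg = aw.PlannerConfig(angle_step_deg=45.0, ray_step_mm=2.0)
        res = aw.plan_single_view(small_field, small_surface, target, geom, cfg)
        base = res.poses[0].base_point
        end = base + res.poses[0].axial * geom.depth_mm
        assert not march_segment_hits_hu(ct, base, target)
        diag = res.candidates
        blocked = [
            row for _, row in diag.iterrows()
            if march_segment_hits_hu(ct, np.array([row.x_mm, row.y_mm, row.z_mm]), target)
        ]
        assert blocked
        assert max(r.t_bar for r in blocked) < res.scores[0]

    def test_single_candidate_is_returned_regardless_of_score(self, small_field, test_probe):
        pt = np.array([[0.0, 42.0, 0.0]])
        nrm = np.array([[0.0, 1.0, 0.0]])
        surf = aw.SurfacePointCloud(pt, nrm, np.ones(3))
        cfg = aw.PlannerConfig(angle_step_deg=45.0, ray_step_mm=2.0)
        res = aw.plan_single_view(small_field, surf, np.array([0.0, 8.0, 0.0]), test_probe, cfg)
        np.testing.assert_array_equal(res.poses[0].base_point, pt[0])

    def test_deterministic_bit_identical(self, small_phantom, small_surface, small_field):
        target = np.array([4.0, 6.0, -5.0])
        geom = aw.ProbeGeometry(n_elements=8, fov_deg=40.0)
        cfg = aw.PlannerConfig(angle_step_deg=45.0, ray_step_mm=2.0)
        r1 = aw.plan_single_view(small_field, small_surface, target, geom, cfg)
        r2 = aw.plan_single_view(small_field, small_surface, target, geom, cfg)
        np.testing.assert_array_equal(r1.poses[0].rotation, r2.poses[0].rotation)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        assert r1.candidates.equals(r2.candidates)


class TestMultiView:
    def test_reduction_to_single_view(self, small_surface, small_field):
        target = np.array([0.0, 8.0, 0.0])
        geom = aw.ProbeGeometry(n_elements=8, fov_deg=40.0)
        cfg = aw.PlannerConfig(angle_step_deg=45.0, ray_step_mm=2.0)
        sv = aw.plan_single_view(small_field, small_surface, target, geom, cfg)
        mv = aw.plan_multi_view(small_field, small_surface, target[None, :], geom, cfg)
        np.testing.assert_array_equal(sv.poses[0].rotation, mv.poses[0].rotation)
        np.testing.assert_array_equal(sv.poses[0].base_point, mv.poses[0].base_point)
        assert sv.poses[0].phi == mv.poses[0].phi
        np.testing.assert_array_equal(sv.scores, mv.scores)

    def test_homogeneous_two_targets_perfect_product(self, test_probe):
        vol = aw.CtVolume(
            np.full((50, 50, 50), 40.0, np.float32), np.full(3, 8.0), -np.full(3, 49 * 4.0)
        )
        field = aw.hu_to_mu(vol)
        surf = _flat_surface(nx=5, nz=5, pitch=8.0, z0=80.0)
        cfg = aw.PlannerConfig(angle_step_deg=45.0, ray_step_mm=4.0)
        targets = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        mv = aw.plan_multi_view(field, surf, targets, test_probe, cfg)
        assert np.exp(mv.score_log_sum) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(mv.poses[0].base_point, mv.poses[1].base_point)

    def test_shared_base_point_and_admissibility(self, small_phantom, small_surface, small_field):
        _, _, targets = small_phantom
        geom = aw.ProbeGeometry(n_elements=8, fov_deg=40.0)
        cfg = aw.PlannerConfig(angle_step_deg=45.0, ray_step_mm=2.0)
        mv = aw.plan_multi_view(small_field, small_surface, targets[:3], geom, cfg)
        bases = np.stack([p.base_point for p in mv.poses])
        assert np.all(bases == bases[0])
        for pose, t in zip(mv.poses, targets[:3]):
            d = np.linalg.norm(t - pose.base_point)
            assert d < geom.depth_mm
            i = int(np.argmin(np.linalg.norm(small_surface.points - pose.base_point, axis=1)))
            cos_in = -pose.axial @ small_surface.normals[i]
            assert np.degrees(np.arccos(np.clip(cos_in, -1, 1))) <= cfg.alpha_deg + 1e-6

    def test_disjoint_targets_raise_with_counts(self, small_surface, small_field):
        geom = aw.ProbeGeometry(n_elements=8, fov_deg=40.0, depth_mm=60.0)
        cfg = aw.PlannerConfig(angle_step_deg=45.0, ray_step_mm=2.0)
        targets = np.array([[0.0, 30.0, 40.0], [0.0, 30.0, -40.0]])
        with pytest.raises(NoAcousticWindowError, match="candidate counts"):
            aw.plan_multi_view(small_field, small_surface, targets, geom, cfg)


class TestNaive:
    def test_flat_surface_picks_point_above_target(self, test_probe):
        surf = _flat_surface()
        res = aw.plan_naive_single(surf, np.array([0.0, 0.0, -50.0]), test_probe)
        np.testing.assert_array_equal(res.poses[0].base_point, [0, 0, 0])
        np.testing.assert_allclose(res.poses[0].axial, [0, 0, -1], atol=1e-12)
        assert np.isnan(res.scores[0])

    def test_lateral_axis_orthogonal_to_axis_and_normal(self, small_surface, test_probe):
        res = aw.plan_naive_single(small_surface, np.array([5.0, 0.0, 10.0]), test_probe)
        pose = res.poses[0]
        i = int(np.argmin(np.linalg.norm(small_surface.points - pose.base_point, axis=1)))
        n = small_surface.normals[i]
        assert abs(pose.lateral @ pose.axial) < 1e-9
        assert abs(pose.lateral @ n) < 1e-9
        assert np.linalg.norm(pose.lateral) == pytest.approx(1.0)

    def test_naive_under_rib_is_beaten_by_planner(self, small_phantom, small_surface, small_field):
        """Place the target right beneath a rib: naive images through bone,
        the transmission-aware pose does not and scores strictly higher."""
        ct, _, _ = small_phantom
        geom = aw.ProbeGeometry(n_elements=5, fov_deg=15.0, depth_mm=90.0)
        cfg = aw.PlannerConfig(angle_step_deg=45.0, ray_step_mm=2.0)
        # rib planes sit at z = {-22, 0, 22}; a target below the central rib
        target = np.array([0.0, 20.0, 0.0])
        naive = aw.plan_naive_single(small_surface, target, geom, small_field, cfg)
        ours = aw.plan_single_view(small_field, small_surface, target, geom, cfg)
        base_n = naive.poses[0].base_point
        assert march_segment_hits_hu(ct, base_n, target)
        assert ours.scores[0] > naive.scores[0]

    @given(st.integers(0, 200))
    def test_rejection_contract(self, k):
        rng = np.random.default_rng(k)
        d_T = rng.normal(size=3)
        d_T /= np.linalg.norm(d_T)
        d_a = rng.normal(size=3)
        d_a /= np.linalg.norm(d_a)
        rej = d_T - d_a * (d_a @ d_T)
        if np.linalg.norm(rej) < 1e-9:
            return
        d_e = rej / np.linalg.norm(rej)
        assert abs(d_e @ d_a) < 1e-9
        assert np.linalg.norm(d_e) == pytest.approx(1.0, abs=1e-12)

    def test_multi_view_parallel_planes_contract(self, small_phantom, small_surface, test_probe):
        _, _, targets = small_phantom
        res = aw.plan_naive_multi(small_surface, targets[:3], test_probe)
        d_T = targets[2] - targets[0]
        d_T /= np.linalg.norm(d_T)
        for pose in res.poses:
            assert abs(pose.elevational @ pose.axial) < 1e-9
            assert np.linalg.norm(pose.elevational) == pytest.approx(1.0, abs=1e-9)

    def test_perpendicular_trajectory_gives_exact_elevational(self, test_probe):
        surf = _flat_surface()
        target = np.array([0.0, 0.0, -50.0])  # d_a = (0,0,-1)
        d_T = np.array([1.0, 0.0, 0.0])  # perpendicular to d_a
        res = aw.plan_naive_multi(surf, target[None, :], test_probe, trajectory_direction=d_T)
        np.testing.assert_allclose(res.poses[0].elevational, d_T, atol=1e-12)

    def test_parallel_trajectory_raises(self, test_probe):
        surf = _flat_surface()
        target = np.array([0.0, 0.0, -50.0])
        with pytest.raises(DegenerateRejectionError, match="target 0"):
            aw.plan_naive_multi(
                surf, target[None, :], test_probe, trajectory_direction=np.array([0.0, 0.0, 1.0])
            )


class TestDominance:
    def test_planner_never_below_naive_on_phantom(self, small_phantom, small_surface, small_field):
        _, _, targets = small_phantom
        geom = aw.ProbeGeometry(n_elements=8, fov_deg=40.0)
        cfg = aw.PlannerConfig(angle_step_deg=15.0, ray_step_mm=2.0)
        for t in targets:
            ours = aw.plan_single_view(small_field, small_surface, t, geom, cfg)
            naive = aw.plan_naive_single(small_surface, t, geom, small_field, cfg)
            assert ours.scores[0] >= naive.scores[0] - 1e-12
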