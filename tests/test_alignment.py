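"""Helmert estimation/application, ICP refinement and cloud merging."""

import numpy as np
import pytest

from bamboostand.alignment import (CoarseAlignmentError, DegenerateControlError, HelmertTransform,
                                   IcpParams, RigidTransform, apply_helmert, estimate_helmert,
                                   icp_refine, merge_clouds)
from bamboostand.cloud import FRAME_LOCAL, FrameError, PointCloud
from bamboostand.io import ControlPointSet
from bamboostand.synthetic import ScannerConfig, StandConfig, generate_stand, render_als


def _control_from(transform, local):
    return ControlPointSet(
        ids=[f"T{i}" for i in range(len(local))],
        local=local,
        projected=transform.apply_points(local),
    )


CORNERS = np.array([[0.0, 0.0, 0.1], [10.0, 0.0, 1.8], [10.0, 10.0, 1.7], [0.0, 10.0, 0.2]])


class TestHelmert:
    def test_identity_parameters_leave_points_unchanged(self):
        t = HelmertTransform.identity()
        pts = np.random.default_rng(0).normal(size=(20, 3))
        np.testing.assert_array_equal(t.apply_points(pts), pts)

    def test_pure_translation(self):
        t = HelmertTransform(dx=1.0, dy=2.0, dz=3.0)
        np.testing.assert_allclose(t.apply_points([[0.0, 0.0, 0.0]]), [[1.0, 2.0, 3.0]])

    def test_scale_only_stretches_norms(self):
        t = HelmertTransform(m=1e-3)
        p = np.array([[1.0, 2.0, 2.0]])
        assert np.linalg.norm(t.apply_points(p)) == pytest.approx((1 + 1e-3) * 3.0)

    def test_apply_then_invert_is_identity(self):
        t = HelmertTransform(dx=5, dy=-3, dz=1, theta_x=0.008, theta_y=-0.004,
                             theta_z=0.009, m=8e-5)
        pts = np.random.default_rng(1).uniform(-0.5, 0.5, size=(50, 3))
        np.testing.assert_allclose(t.inverse_points(t.apply_points(pts)), pts, atol=1e-9)

    def test_estimate_identity_from_identical_pairs(self):
        transform, report = estimate_helmert(_control_from(HelmertTransform.identity(), CORNERS))
        np.testing.assert_allclose(transform.as_array(), np.zeros(7), atol=1e-12)
        assert report.rms_m < 1e-12

    def test_estimate_recovers_known_parameters(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            params = np.concatenate([
                rng.uniform(-100, 100, 3),
                rng.uniform(-0.01, 0.01, 3),
                rng.uniform(-1e-4, 1e-4, 1),
            ])
            truth = HelmertTransform.from_array(params)
            est, _ = estimate_helmert(_control_from(truth, CORNERS))
            np.testing.assert_allclose(est.as_array(), params, atol=1e-8)

    def test_noisy_controls_leave_noise_scale_residuals(self):
        rng = np.random.default_rng(3)
        truth = HelmertTransform(dx=20, dy=-7, dz=3, theta_x=0.002, theta_y=0.001,
                                 theta_z=-0.003, m=3e-5)
        rms_values = []
        for _ in range(30):
            noisy = ControlPointSet(
                ids=["a", "b", "c", "d"],
                local=CORNERS,
                projected=truth.apply_points(CORNERS) + rng.normal(0, 0.05, size=(4, 3)),
            )
            _, report = estimate_helmert(noisy)
            rms_values.append(report.rms_m)
        mean_rms = np.mean(rms_values)
        assert 0.005 < mean_rms < 0.1  # on the order of the 0.05 m noise

    def test_collinear_controls_rejected(self):
        line = np.column_stack([np.arange(4.0), np.arange(4.0) * 2, np.zeros(4)])
        with pytest.raises(DegenerateControlError):
            estimate_helmert(_control_from(HelmertTransform.identity(), line))

    def test_estimated_transform_maps_controls_exactly(self):
        truth = HelmertTransform(dx=12, dy=8, dz=-2, theta_x=-0.004, theta_y=0.006,
                                 theta_z=0.002, m=-5e-5)
        control = _control_from(truth, CORNERS)
        est, _ = estimate_helmert(control)
        np.testing.assert_allclose(est.apply_points(control.local), control.projected, atol=1e-8)

    def test_apply_helmert_requires_local_frame(self):
        cloud = PointCloud(np.zeros((3, 3)))  # projected by default
        with pytest.raises(FrameError):
            apply_helmert(HelmertTransform.identity(), cloud)
        local = PointCloud(np.zeros((3, 3)), frame=FRAME_LOCAL)
        out = apply_helmert(HelmertTransform(dx=1), local)
        assert out.frame == "projected"
        np.testing.assert_allclose(out.x, 1.0)


@pytest.fixture(scope="module")
def stand_cloud():
    truth = generate_stand(StandConfig(n_plants=10, min_spacing_m=1.5, seed=21))
    return render_als(truth, ScannerConfig.als(seed=22))


class TestIcp:

    def test_source_equals_target_gives_identity(self, stand_cloud):
        res = icp_refine(stand_cloud, stand_cloud, IcpParams(voxel_size_m=None))
        assert res.rms_m < 1e-9
        np.testing.assert_allclose(res.transform.R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.transform.t, 0.0, atol=1e-9)

    def test_recovers_small_rigid_perturbation(self, stand_cloud):
        angle = np.radians(2.0)
        R = np.array([[np.cos(angle), -np.sin(angle), 0.0],
                      [np.sin(angle), np.cos(angle), 0.0],
                      [0.0, 0.0, 1.0]])
        t = np.array([0.15, -0.1, 0.08])
        perturbed = stand_cloud.with_xyz(stand_cloud.xyz @ R.T + t)
        res = icp_refine(perturbed, stand_cloud, IcpParams(voxel_size_m=None, tol_m=1e-10))
        combined = RigidTransform(res.transform.R @ R, res.transform.R @ t + res.transform.t)
        assert combined.rotation_angle_rad() < 1e-4
        assert np.linalg.norm(combined.t) < 1e-4
        assert all(b <= a + 1e-12 for a, b in zip(res.rms_history, res.rms_history[1:]))

    def test_poor_coarse_alignment_raises(self, stand_cloud):
        far = stand_cloud.with_xyz(stand_cloud.xyz + 100.0)
        with pytest.raises(CoarseAlignmentError):
            icp_refine(far, stand_cloud, IcpParams(rejection_radius_m=0.5))


class TestMerge:
    def test_counts_and_tags_preserved(self):
        a = PointCloud(np.zeros((3, 3)), attrs={"source": np.array(["als"] * 3)})
        b = PointCloud(np.ones((2, 3)), attrs={"source": np.array(["tls"] * 2)})
        merged = merge_clouds(a, b)
        assert len(merged) == 5
        assert (merged.attrs["source"] == "als").sum() == 3
        assert (merged.attrs["source"] == "tls").sum() == 2

    def test_merge_with_empty_is_identity(self):
        a = PointCloud(np.random.default_rng(0).normal(size=(4, 3)))
        merged = merge_clouds(a, PointCloud(np.empty((0, 3))))
        np.testing.assert_array_equal(merged.xyz, a.xyz)

    def test_frame_mismatch_rejected(self):
        a = PointCloud(np.zeros((1, 3)))
        b = PointCloud(np.zeros((1, 3)), frame=FRAME_LOCAL)
        with pytest.raises(FrameError):
            merge_clouds(a, b)
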