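"""PCS and CSP segmentation against generator-label oracles."""

import numpy as np
import pytest

from bamboostand.cloud import PointCloud
from bamboostand.segmentation import (CspParams, CulmDetectionError, PcsParams, SegmentationError,
                                      detect_culms, extract_height, segment_csp,
                                      segment_csp_double, segment_pcs)
from bamboostand.synthetic import ScannerConfig, StandConfig, StandTruth, generate_stand, render_als, render_tls

from conftest import normalized_truth_cloud


def make_truth(bases, dbh=0.1, height=12.0, crown_radius=0.8, lean=None,
               plot=(6.0, 6.0), slope=5.0):
    """Hand-built stand truth for constructed segmentation fixtures."""
    bases = np.asarray(bases, dtype=float)
    n = len(bases)
    cfg = StandConfig(plot_size_m=plot, n_plants=n, ground_slope_deg=slope, seed=0)
    truth = StandTruth(
        config=cfg,
        ids=np.arange(1, n + 1),
        base_xy=bases,
        dbh_m=np.full(n, dbh, dtype=float),
        height_m=np.broadcast_to(np.asarray(height, dtype=float), (n,)).copy(),
        crown_radius_m=np.full(n, crown_radius, dtype=float),
        lean_xy=np.zeros((n, 2)) if lean is None else np.asarray(lean, dtype=float),
        corner_targets=np.zeros((4, 3)),
    )
    corners = np.array([[0.0, 0.0], [plot[0], 0.0], list(plot), [0.0, plot[1]]])
    truth.corner_targets = np.column_stack([corners, truth.ground_z(corners)])
    return truth


def _purity(segments, cloud):
    """Fraction of assigned points whose segment's majority plant matches their label."""
    correct = total = 0
    for seg in segments:
        labels = cloud.attrs["plant"][seg.indices]
        labels = labels[labels >= 0]
        if len(labels) == 0:
            continue
        vals, counts = np.unique(labels, return_counts=True)
        correct += counts.max()
        total += len(labels)
    return correct / total


class TestPcs:
    def test_two_crowns_far_apart_give_two_pure_segments(self):
        truth = make_truth([[1.5, 3.0], [4.5, 3.0]], crown_radius=0.5)
        cloud = normalized_truth_cloud(truth, render_als(truth, ScannerConfig.als(seed=1)))
        segments = segment_pcs(cloud, PcsParams(d=1.0))
        assert len(segments) == 2
        assert _purity(segments, cloud) > 0.99

    def test_single_plant_contains_global_maximum(self):
        truth = make_truth([[3.0, 3.0]])
        cloud = normalized_truth_cloud(truth, render_als(truth, ScannerConfig.als(seed=2)))
        segments = segment_pcs(cloud, PcsParams(d=1.5))
        assert len(segments) == 1
        assert np.argmax(cloud.z) in segments[0].indices

    def test_highest_point_seeds_segment_one(self, small_truth, small_als):
        cloud = normalized_truth_cloud(small_truth, small_als)
        segments = segment_pcs(cloud, PcsParams(d=1.5))
        top = segments[0].indices[np.argmax(cloud.z[segments[0].indices])]
        assert top == np.argmax(cloud.z)

    def test_partition_property(self, small_truth, small_als):
        cloud = normalized_truth_cloud(small_truth, small_als)
        segments = segment_pcs(cloud, PcsParams(d=1.5))
        all_idx = np.concatenate([s.indices for s in segments])
        assert len(all_idx) == len(set(all_idx))  # no point in two segments
        assert len(all_idx) <= len(cloud)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            PcsParams(d=0.0).validate()


class TestDetectCulms:
    def test_well_spaced_culms_found_at_their_bases(self, small_truth, small_tls_projected):
        cloud = normalized_truth_cloud(small_truth, small_tls_projected)
        culms = detect_culms(cloud, CspParams())
        assert len(culms) == small_truth.n_plants
        centroids = np.array([c.base_xy for c in culms])
        # culm band centre is ~1.25 m up a slightly leaning culm
        band_mid_xy = np.array([
            small_truth.culm_axis_xy(i, np.array([1.25]))[0]
            for i in range(small_truth.n_plants)
        ])
        d = np.linalg.norm(centroids[:, None] - band_mid_xy[None, :], axis=2)
        assert (d.min(axis=1) < 0.05).all()

    def test_sparse_als_culm_layer_underdetects(self, small_truth, small_als):
        cloud = normalized_truth_cloud(small_truth, small_als)
        try:
            culms = detect_culms(cloud, CspParams())
            assert len(culms) < small_truth.n_plants
        except CulmDetectionError:
            pass  # zero clusters is the expected failure mode for airborne data

    def test_uniform_noise_has_no_cluster(self):
        rng = np.random.default_rng(0)
        cloud = PointCloud(rng.uniform([0, 0, 0], [10, 10, 3], size=(3000, 3)))
        cloud.meta["normalized"] = True
        with pytest.raises(CulmDetectionError):
            detect_culms(cloud, CspParams())

    def test_empty_band_raises(self):
        cloud = PointCloud(np.column_stack([np.random.default_rng(1).uniform(0, 5, (100, 2)),
                                            np.full(100, 5.0)]))
        cloud.meta["normalized"] = True
        with pytest.raises(CulmDetectionError, match="culm band"):
            detect_culms(cloud, CspParams())


class TestCsp:
    def test_two_separated_plants_fully_correct(self):
        truth = make_truth([[1.5, 3.0], [4.5, 3.0]], crown_radius=0.6)
        tls, _ = render_tls(truth, ScannerConfig.tls(seed=3, density_pts_per_m2=4000))
        cloud = normalized_truth_cloud(truth, tls.with_xyz(tls.xyz, frame="projected"))
        culms = detect_culms(cloud, CspParams())
        segments = segment_csp(cloud, culms, CspParams())
        assert len(segments) == 2
        assert _purity(segments, cloud) > 0.995

    def test_single_culm_takes_everything(self):
        truth = make_truth([[3.0, 3.0]])
        tls, _ = render_tls(truth, ScannerConfig.tls(seed=4, density_pts_per_m2=3000))
        cloud = normalized_truth_cloud(truth, tls.with_xyz(tls.xyz, frame="projected"))
        culms = detect_culms(cloud, CspParams())
        segments = segment_csp(cloud, culms, CspParams())
        assert len(segments) == 1
        in_scope = (cloud.z >= CspParams().min_height_m).sum()
        assert len(segments[0].indices) == in_scope

    def test_paths_beat_horizontal_nearest_for_interlocked_leaning_pair(self):
        # a taller plant leaning over its shorter neighbour: the overhanging
        # crown and the crossed upper culm sit horizontally nearer the wrong
        # culm, but stay path-connected to their own
        lean = np.array([[0.045, 0.0], [-0.02, 0.0]])
        truth = make_truth([[2.2, 3.0], [3.0, 3.0]], height=[13.0, 10.0],
                           crown_radius=0.7, lean=lean)
        tls, _ = render_tls(truth, ScannerConfig.tls(seed=5, density_pts_per_m2=4000,
                                                     culm_gap_deg=0.0, top_cut_range=None))
        cloud = normalized_truth_cloud(truth, tls.with_xyz(tls.xyz, frame="projected"))
        culms = detect_culms(cloud, CspParams())
        assert len(culms) == 2
        segments = segment_csp(cloud, culms, CspParams())
        path_acc = _purity(segments, cloud)
        # naive: nearest culm centroid in the horizontal plane
        bases = np.array([c.base_xy for c in culms])
        in_scope = cloud.z >= CspParams().min_height_m
        d = np.linalg.norm(cloud.xy[in_scope, None] - bases[None], axis=2)
        naive_assign = np.argmin(d, axis=1)
        labels = cloud.attrs["plant"][in_scope]
        # map culm index -> majority truth plant
        naive_correct = 0
        for ci in range(2):
            sel = naive_assign == ci
            vals, counts = np.unique(labels[sel], return_counts=True)
            naive_correct += counts.max()
        naive_acc = naive_correct / in_scope.sum()
        assert path_acc > naive_acc

    def test_order_invariance_of_assignment(self):
        truth = make_truth([[2.0, 3.0], [4.0, 3.0]], crown_radius=0.7)
        tls, _ = render_tls(truth, ScannerConfig.tls(seed=6, density_pts_per_m2=2500))
        cloud = normalized_truth_cloud(truth, tls.with_xyz(tls.xyz, frame="projected"))
        perm = np.random.default_rng(7).permutation(len(cloud))
        shuffled = cloud.select(perm)
        seg_a = segment_csp(cloud, detect_culms(cloud, CspParams()), CspParams())
        seg_b = segment_csp(shuffled, detect_culms(shuffled, CspParams()), CspParams())
        for a, b in zip(seg_a, seg_b):
            assert set(perm[b.indices]) == set(a.indices)


class TestDoublePass:
    def test_separated_stand_is_fixed_point(self, small_truth, small_tls_projected):
        cloud = normalized_truth_cloud(small_truth, small_tls_projected)
        params = CspParams()
        first = segment_csp(cloud, detect_culms(cloud, params), params)
        final, info = segment_csp_double(cloud, params)
        assert info["converged"] is True
        assert len(final) == len(first)

    def test_undersegmented_pair_is_split_in_pass_two(self):
        # bases 0.25 m apart: surfaces chain at the default radius but separate
        # at the finer second-pass radius
        truth = make_truth([[2.85, 3.0], [3.1, 3.0]], dbh=0.09, crown_radius=0.6)
        tls, _ = render_tls(truth, ScannerConfig.tls(seed=8, density_pts_per_m2=6000,
                                                     culm_gap_deg=0.0))
        cloud = normalized_truth_cloud(truth, tls.with_xyz(tls.xyz, frame="projected"))
        params = CspParams()
        first_culms = detect_culms(cloud, params)
        assert len(first_culms) == 1  # merged at eps = 0.2
        final, info = segment_csp_double(cloud, params)
        assert len(final) >= 2
        assert info["second_pass_splits"] >= 1


class TestHeights:
    def test_height_reads_max_member_z(self, small_truth, small_als):
        cloud = normalized_truth_cloud(small_truth, small_als)
        segments = segment_pcs(cloud, PcsParams(d=1.5))
        for seg in segments:
            assert extract_height(seg, cloud) == pytest.approx(cloud.z[seg.indices].max())

    def test_dense_als_height_close_to_truth(self, small_truth, small_als):
        cloud = normalized_truth_cloud(small_truth, small_als)
        segments = segment_pcs(cloud, PcsParams(d=1.8))
        by_pos = {tuple(np.round(s.culm_base_xy, 0)): s for s in segments}
        hits = 0
        for i in range(small_truth.n_plants):
            for seg in segments:
                if np.linalg.norm(seg.culm_base_xy - small_truth.base_xy[i]) < 1.0:
                    assert abs(extract_height(seg, cloud) - small_truth.height_m[i]) < 0.3
                    hits += 1
                    break
        assert hits >= small_truth.n_plants // 2

    def test_tls_height_biased_low_vs_merged(self, small_truth, small_als, small_tls_projected):
        """Crown-top sparsity: TLS max-z underestimates; adding ALS recovers it."""
        from bamboostand.alignment import merge_clouds

        tls_n = normalized_truth_cloud(small_truth, small_tls_projected)
        merged_n = normalized_truth_cloud(small_truth, merge_clouds(small_als, small_tls_projected))
        tls_bias = []
        for i, pid in enumerate(small_truth.ids):
            t_est = tls_n.z[tls_n.attrs["plant"] == pid].max()
            m_est = merged_n.z[merged_n.attrs["plant"] == pid].max()
            truth_h = small_truth.height_m[i]
            assert m_est >= t_est
            tls_bias.append(truth_h - t_est)
        assert np.mean(tls_bias) > 0.1  # systematically short
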