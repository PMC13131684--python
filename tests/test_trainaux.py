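import numpy as np
import pytest

from mveks.geometry import project, reprojection_error, triangulate_multiview
from mveks.synthetic import make_rig
from mveks.trainaux import (
    Augment3DParams,
    heatmap_expectation,
    MaskSchedule,
    augment_3d,
    fit_similarity,
    gaussian_heatmap,
    mask_fraction,
    reprojection_loss,
    sample_patch_mask,
    soft_argmax,
    spatial_softmax,
)


class TestSoftArgmax:
    def test_one_hot_peak_high_temperature(self):
        h = np.zeros((12, 10))
        h[7, 3] = 1.0
        coords, conf = soft_argmax(h, temperature=1000.0)
        assert np.allclose(coords, [3.0, 7.0], atol=1e-6)
        assert conf > 0.999

    def test_two_equal_peaks_give_midpoint(self):
        h = np.zeros((5, 11))
        h[2, 2] = 1.0
        h[2, 8] = 1.0
        coords, _ = soft_argmax(h, temperature=1.0)
        assert np.isclose(coords[0], 5.0)
        assert np.isclose(coords[1], 2.0)

    def test_matches_weighted_average_oracle(self):
        rng = np.random.default_rng(0)
        h = rng.uniform(size=(9, 13))
        coords, conf = soft_argmax(h, temperature=1.0, confidence_radius=2.5)
        p = np.exp(h)
        p /= p.sum()
        ys, xs = np.mgrid[0:9, 0:13]
        ex = (p * xs).sum()
        ey = (p * ys).sum()
        assert np.allclose(coords, [ex, ey], atol=1e-8)
        mask = (xs - ex) ** 2 + (ys - ey) ** 2 <= 2.5**2
        assert np.isclose(conf, p[mask].sum(), atol=1e-8)

    def test_all_equal_map_returns_grid_centroid(self):
        coords, _ = soft_argmax(np.ones((7, 9)), temperature=5.0)
        assert np.allclose(coords, [4.0, 3.0])

    @pytest.mark.parametrize("temperature", [0.5, 1.0, 50.0])
    def test_softmax_sums_to_one(self, temperature):
        rng = np.random.default_rng(1)
        p = spatial_softmax(rng.uniform(size=(3, 8, 8)), temperature)
        assert np.allclose(p.sum(axis=(-2, -1)), 1.0, atol=1e-6)

    def test_flip_equivariance(self):
        rng = np.random.default_rng(2)
        h = rng.uniform(size=(10, 14))
        c, _ = soft_argmax(h, temperature=2.0)
        c_lr, _ = soft_argmax(h[:, ::-1], temperature=2.0)
        c_ud, _ = soft_argmax(h[::-1, :], temperature=2.0)
        assert np.isclose(c_lr[0], 13 - c[0], atol=1e-8)
        assert np.isclose(c_ud[1], 9 - c[1], atol=1e-8)


class TestGaussianHeatmap:
    def test_soft_argmax_roundtrip_with_upsampling(self):
        pts = np.array([[10.3, 17.8], [5.1, 4.9]])
        stack = gaussian_heatmap(pts, 32, 24, sigma=1.25)
        coords, _ = soft_argmax(stack.values, temperature=1000.0, upsample=8)
        assert np.all(np.abs(coords - pts) < 0.1)

    def test_density_mean_roundtrip_is_subpixel_exact(self):
        pts = np.array([[10.3, 17.8], [5.1, 4.9]])
        stack = gaussian_heatmap(pts, 32, 24, sigma=1.25)
        coords = heatmap_expectation(stack.values)
        assert np.all(np.abs(coords - pts) < 1e-4)

    def test_peak_at_nearest_grid_point(self):
        stack = gaussian_heatmap(np.array([[10.4, 6.7]]), 16, 16)
        k = stack.values[0]
        assert k[7, 10] == k.max()

    def test_far_outside_coords_give_near_zero_map(self):
        stack = gaussian_heatmap(np.array([[500.0, 500.0]]), 16, 16)
        assert stack.values.max() < 1e-6

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_heatmap(np.array([[1.0, 1.0]]), 8, 8, sigma=0.0)


class TestReprojectionLoss:
    def _consistent_stacks(self, rig, pts3d, h=64, w=64, scale=4.0):
        stacks = []
        for cam in rig:
            px = project(cam, pts3d)
            stacks.append(gaussian_heatmap(px / scale, h, w, scale=scale))
        return stacks

    def test_zero_on_consistent_scene(self, ring_rig):
        pts = np.array([[0.1, 0.2, -0.1], [-0.2, 0.1, 0.3]])
        # centre the grid on the image so the maps have mass
        stacks = self._consistent_stacks(ring_rig, pts, h=128, w=160)
        loss = reprojection_loss(stacks, stacks, ring_rig)
        assert loss < 1e-10

    def test_matches_stage_by_stage_oracle(self):
        from mveks.geometry import CameraRig

        rig = CameraRig(make_rig(n_views=4).cameras[:2])
        pts = np.array([[0.05, 0.1, 0.0]])
        h, w, scale = 128, 160, 4.0
        gt = self._consistent_stacks(rig, pts, h, w, scale)
        # displaced prediction in view 1
        px0 = project(rig[0], pts) / scale
        px1 = project(rig[1], pts) / scale + np.array([2.0, -1.5])
        pred = [gaussian_heatmap(px0, h, w, scale=scale), gaussian_heatmap(px1, h, w, scale=scale)]
        loss = reprojection_loss(pred, gt, rig)
        # oracle: explicit five-stage chain
        c0 = heatmap_expectation(pred[0].values)
        c1 = heatmap_expectation(pred[1].values)
        obs = np.stack([c0 * scale, c1 * scale])
        tri = triangulate_multiview(rig, obs)
        total, count = 0.0, 0
        for v in range(2):
            reproj = project(rig[v], tri) / scale
            regen = gaussian_heatmap(reproj, h, w, scale=scale)
            total += np.mean((regen.values[0] - gt[v].values[0]) ** 2) * h * w
            count += 1
        assert np.isclose(loss, total / count, rtol=1e-10)

    def test_invariant_to_keypoint_order(self, ring_rig):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-0.2, 0.2, (3, 3))
        h, w, scale = 128, 160, 4.0
        gt = self._consistent_stacks(ring_rig, pts, h, w, scale)
        pred = []
        for cam in ring_rig:
            px = project(cam, pts) / scale + rng.normal(0, 1, (3, 2))
            pred.append(gaussian_heatmap(px, h, w, scale=scale))
        loss = reprojection_loss(pred, gt, ring_rig)
        perm = [2, 0, 1]
        gt_p = [gaussian_heatmap(heatmap_expectation(s.values)[perm], h, w, scale=scale) for s in gt]
        pred_p = [
            gaussian_heatmap(heatmap_expectation(s.values)[perm], h, w, scale=scale)
            for s in pred
        ]
        loss_p = reprojection_loss(pred_p, gt_p, ring_rig)
        assert np.isclose(loss, loss_p, rtol=1e-6)


class TestMaskCurriculum:
    @pytest.mark.parametrize(
        "iteration,expected", [(0, 0.0), (699, 0.0), (700, 0.10), (5000, 0.50), (9000, 0.50)]
    )
    def test_schedule_values(self, iteration, expected):
        assert np.isclose(mask_fraction(MaskSchedule(), iteration), expected)

    def test_nondecreasing_in_iteration(self):
        sched = MaskSchedule()
        fracs = [mask_fraction(sched, i) for i in range(0, 6000, 37)]
        assert np.all(np.diff(fracs) >= 0)

    def test_nondecreasing_for_arbitrary_schedules(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, derandomize=True, deadline=None)
        @given(
            start=st.integers(0, 1000),
            span=st.integers(1, 5000),
            f0=st.floats(0, 1),
            f1=st.floats(0, 1),
            i=st.integers(0, 10000),
            j=st.integers(0, 10000),
        )
        def check(start, span, f0, f1, i, j):
            lo, hi = sorted((f0, f1))
            sched = MaskSchedule(start, lo, start + span, hi)
            a, b = sorted((i, j))
            assert mask_fraction(sched, a) <= mask_fraction(sched, b) + 1e-12

        check()

    def test_zero_fraction_all_false(self):
        mask = sample_patch_mask(16, 16, 0.0, np.random.default_rng(0))
        assert not mask.any()

    def test_full_fraction_all_true(self):
        mask = sample_patch_mask(16, 16, 1.0, np.random.default_rng(0))
        assert mask.all()

    def test_half_fraction_realized_within_one_block(self):
        rng = np.random.default_rng(3)
        mask = sample_patch_mask(16, 16, 0.5, rng, max_block=4)
        frac = mask.mean()
        assert 0.5 <= frac <= 0.5 + 16.0 / 256.0

    def test_reproducible_under_seed(self):
        a = sample_patch_mask(16, 16, 0.3, np.random.default_rng(42))
        b = sample_patch_mask(16, 16, 0.3, np.random.default_rng(42))
        assert np.array_equal(a, b)


class TestAugment3D:
    def test_similarity_fit_recovers_known_transform(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(-10, 10, (8, 2))
        s, th = 1.3, 0.4
        R = s * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = np.array([2.0, -5.0])
        dst = src @ R.T + t
        M = fit_similarity(src, dst)
        assert np.allclose(M[:, :2], R, atol=1e-10)
        assert np.allclose(M[:, 2], t, atol=1e-10)

    def test_identity_draws_are_identity(self, ring_rig):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-0.3, 0.3, (5, 3))
        labels = np.stack([project(c, pts) for c in ring_rig])
        out, transforms, aug3d = augment_3d(labels, ring_rig, scale=1.0, shift=np.zeros(3))
        assert np.allclose(out, labels, atol=1e-8)
        for M in transforms:
            assert np.allclose(M, [[1, 0, 0], [0, 1, 0]], atol=1e-6)

    def test_augmented_labels_triangulate_to_augmented_3d(self, ring_rig):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-0.3, 0.3, (5, 3))
        labels = np.stack([project(c, pts) for c in ring_rig])
        out, _, aug3d = augment_3d(labels, ring_rig, rng=np.random.default_rng(7))
        rec = triangulate_multiview(ring_rig, out)
        assert np.allclose(rec, aug3d, atol=1e-5)

    def test_preserves_cross_view_consistency(self, ring_rig):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-0.3, 0.3, (4, 3))
        labels = np.stack([project(c, pts) for c in ring_rig])
        out, _, aug3d = augment_3d(labels, ring_rig, rng=np.random.default_rng(11))
        _, mean_err = reprojection_error(ring_rig, out, aug3d)
        assert np.nanmax(mean_err) < 1e-6

    def test_untriangulable_keypoint_passes_through(self, ring_rig):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-0.3, 0.3, (3, 3))
        labels = np.stack([project(c, pts) for c in ring_rig])
        labels[1:, 0] = np.nan  # keypoint 0 visible in one view only
        out, _, aug3d = augment_3d(labels, ring_rig, rng=np.random.default_rng(0))
        assert np.allclose(out[0, 0], labels[0, 0], equal_nan=True)
        assert np.all(np.isnan(aug3d[0]))
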