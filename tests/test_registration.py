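"""Slope computation, the mode filter, RANSAC baseline, transforms, warps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shadowcwsi.errors import (
    DegenerateGeometryError,
    InsufficientMatchesError,
)
from shadowcwsi.registration import (
    MatchSet,
    PlanarTransform,
    compute_slopes,
    detect_and_match,
    estimate_transform,
    ransac_filter,
    slope_mode_filter,
    warp_mask,
)
from shadowcwsi.synthetic import generate_match_fixture


def matchset(pts_a, pts_b, offset=0.0):
    return compute_slopes(MatchSet(np.array(pts_a, float),
                                   np.array(pts_b, float),
                                   canvas_offset=offset))


class TestSlopeFormula:
    def test_printed_substitution(self):
        m = matchset([(0, 0)], [(10, 5)])
        assert m.slopes[0] == pytest.approx(0.5)

    def test_zero_denominator_gets_infinite_sentinel(self):
        m = matchset([(5, 5)], [(5, 9)])
        assert np.isinf(m.slopes[0])

    def test_canvas_offset_enters_denominator(self):
        m = matchset([(0, 0)], [(10, 5)], offset=90.0)
        assert m.slopes[0] == pytest.approx(5 / 100)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(
        st.tuples(st.floats(-100, 100), st.floats(-100, 100),
                  st.floats(-100, 100), st.floats(-100, 100)),
        min_size=3, max_size=20))
    def test_swap_antisymmetry(self, quads):
        """Swapping image roles negates both deltas; kept set is invariant."""
        a = np.array([(q[0], q[1]) for q in quads])
        b = np.array([(q[2], q[3]) for q in quads])
        fwd = compute_slopes(MatchSet(a, b, canvas_offset=0.0))
        rev = compute_slopes(MatchSet(b, a, canvas_offset=0.0))
        finite = np.isfinite(fwd.slopes)
        np.testing.assert_allclose(rev.slopes[finite], fwd.slopes[finite],
                                   rtol=1e-9)
        if finite.sum() >= 3:
            kept_f, _ = slope_mode_filter(fwd)
            kept_r, _ = slope_mode_filter(rev)
            np.testing.assert_array_equal(kept_f.inlier, kept_r.inlier)


class TestSlopeModeFilter:
    def test_mode_by_majority(self):
        m = MatchSet(np.zeros((4, 2)), np.zeros((4, 2)), canvas_offset=0.0,
                     slopes=np.array([0.50, 0.50, 0.50, 0.90]))
        kept, stats = slope_mode_filter(m, bin_width=0.02, tolerance=0.1)
        assert list(kept.inlier) == [True, True, True, False]
        assert abs(stats.mode - 0.50) <= 0.02

    def test_all_equal_slopes_all_kept(self):
        m = MatchSet(np.zeros((5, 2)), np.zeros((5, 2)), canvas_offset=0.0,
                     slopes=np.full(5, 0.25))
        kept, stats = slope_mode_filter(m)
        assert kept.inlier.all()
        assert stats.mode == stats.mean == stats.median == 0.25

    def test_stats_ordering_invariants(self):
        rng = np.random.default_rng(5)
        m = MatchSet(np.zeros((50, 2)), np.zeros((50, 2)), canvas_offset=0.0,
                     slopes=rng.normal(0, 1, 50))
        _, s = slope_mode_filter(m)
        assert s.min <= s.median <= s.max
        assert s.min <= s.mode <= s.max
        assert abs(s.mode - s.median) <= s.max - s.min

    def test_planted_outliers_removed(self):
        m, labels = generate_match_fixture(100, 40, true_shift=(12, -7),
                                           noise_sd=0.4, seed=11)
        kept, stats = slope_mode_filter(m)
        sensitivity = (kept.inlier & labels).sum() / labels.sum()
        assert sensitivity >= 0.95
        tol = 2 * stats.bin_width
        assert (np.abs(m.slopes[kept.inlier] - stats.mode) <= tol).all()

    def test_deterministic(self):
        m, _ = generate_match_fixture(60, 30, true_shift=(5, 9),
                                      noise_sd=0.5, seed=2)
        k1, s1 = slope_mode_filter(m)
        k2, s2 = slope_mode_filter(m)
        np.testing.assert_array_equal(k1.inlier, k2.inlier)
        assert s1.mode == s2.mode

    def test_all_infinite_slopes_degenerate(self):
        m = MatchSet(np.zeros((3, 2)), np.zeros((3, 2)), canvas_offset=0.0,
                     slopes=np.full(3, np.inf))
        with pytest.raises(DegenerateGeometryError):
            slope_mode_filter(m)


class TestRansac:
    def test_perfect_correspondences_all_inliers(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 100, (30, 2))
        t = PlanarTransform("affine", [[1.1, 0.05, 3], [-0.02, 0.95, -2],
                                       [0, 0, 1]])
        m = MatchSet(t(src), src, canvas_offset=0.0)
        out = ransac_filter(m, model="affine", threshold=1.0, seed=0)
        assert out.inlier.all()

    def test_planted_outliers_rejected(self):
        m, labels = generate_match_fixture(50, 50, true_shift=(20, 4),
                                           noise_sd=0.2, seed=3)
        out = ransac_filter(m, model="similarity", threshold=2.0, seed=0)
        np.testing.assert_array_equal(out.inlier, labels)


class TestEstimateTransform:
    def test_exact_homography_recovered(self):
        h_true = np.array([[1.2, 0.1, 5.0], [0.05, 0.9, -3.0],
                           [1e-4, -2e-4, 1.0]])
        t_true = PlanarTransform("homography", h_true)
        src = np.array([[0, 0], [100, 0], [0, 80], [100, 80]], float)
        m = MatchSet(t_true(src), src, canvas_offset=0.0)
        t = estimate_transform(m, model="homography")
        norm = t.matrix / t.matrix[2, 2]
        np.testing.assert_allclose(norm, h_true, rtol=1e-6, atol=1e-6)

    def test_noisy_translation_recovered(self):
        rng = np.random.default_rng(4)
        src = rng.uniform(0, 200, (50, 2))
        dst = src + [7.5, -3.25] + rng.normal(0, 0.2, (50, 2))
        m = MatchSet(dst, src, canvas_offset=0.0)
        t = estimate_transform(m, model="translation")
        np.testing.assert_allclose(t.matrix[:2, 2], [7.5, -3.25], atol=0.1)

    def test_collinear_points_degenerate(self):
        src = np.array([[0, 0], [1, 1], [2, 2]], float)
        m = MatchSet(src, src, canvas_offset=0.0)
        with pytest.raises(DegenerateGeometryError):
            estimate_transform(m, model="affine")


class TestDetectAndMatch:
    def test_self_match_slopes_zero(self):
        rng = np.random.default_rng(0)
        img = rng.random((128, 128))
        m = detect_and_match(img, img)
        assert m.canvas_offset == 128.0
        assert np.abs(m.slopes[np.isfinite(m.slopes)]).max() < 1e-12

    def test_shifted_copy_gives_tight_slope_cluster(self):
        rng = np.random.default_rng(1)
        base = rng.random((160, 160))
        from scipy import ndimage
        shifted = np.roll(base, 12, axis=0)  # shift down by 12 rows
        m = detect_and_match(base, shifted)
        kept, stats = slope_mode_filter(m)
        expected = 12 / 160.0  # dy / canvas width, to first order
        assert abs(stats.mode - expected) <= 4 * stats.bin_width
        finite = m.slopes[kept.inlier]
        assert finite.std() < stats.bin_width

    def test_blank_pair_insufficient_matches(self):
        blank = np.zeros((64, 64))
        with pytest.raises(InsufficientMatchesError):
            detect_and_match(blank, blank)


class TestWarpMask:
    def test_identity_transform_unchanged(self):
        mask = np.random.default_rng(2).random((40, 40)) > 0.5
        t = PlanarTransform("translation", np.eye(3))
        warped, valid = warp_mask(mask, t, (40, 40))
        np.testing.assert_array_equal(warped, mask)
        assert valid.all()

    def test_integer_translation_exact_shift(self):
        mask = np.zeros((30, 30), bool)
        mask[10:14, 5:9] = True
        t = PlanarTransform("translation",
                            [[1, 0, 3], [0, 1, 2], [0, 0, 1]])
        warped, valid = warp_mask(mask, t, (30, 30))
        # thermal (x,y) maps to source (x+3, y+2): pullback shifts up-left
        assert warped[8:12, 2:6].all()
        assert warped.sum() == mask.sum()

    def test_out_of_frame_marked_invalid_not_false(self):
        mask = np.ones((10, 10), bool)
        t = PlanarTransform("translation",
                            [[1, 0, 8], [0, 1, 0], [0, 0, 1]])
        warped, valid = warp_mask(mask, t, (10, 10))
        assert not valid[:, 2:].any()
        assert valid[:, :2].all()

    def test_round_trip_similarity(self):
        rng = np.random.default_rng(8)
        mask = rng.random((64, 64)) > 0.4
        t = PlanarTransform(
            "similarity",
            [[1.05, 0.02, 2.0], [-0.02, 1.05, -1.5], [0, 0, 1]])
        fwd, valid1 = warp_mask(mask, t, (64, 64))
        back, valid2 = warp_mask(fwd, t.inverse(), (64, 64))
        interior = valid1 & valid2
        interior[:3] = interior[-3:] = False
        interior[:, :3] = interior[:, -3:] = False
        agreement = (back == mask)[interior].mean()
        assert agreement >= 0.9


def test_registration_recovery_on_scene(scene, registered):
    """Known translation+scale recovered to <= 1 px mean grid error."""
    t, matches, stats = registered
    ht, wt = scene.thermal.shape
    yy, xx = np.mgrid[5:ht - 5:15, 5:wt - 5:15]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    err = np.linalg.norm(t(grid) - scene.true_transform(grid), axis=1)
    assert err.mean() <= 1.0
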