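"""K-means++ clustering, cluster-role rules and mask construction."""

import itertools

import numpy as np
import pytest

from shadowcwsi.errors import ValidationError
from shadowcwsi.raster_io import MultibandImage
from shadowcwsi.segmentation import (
    build_canopy_internal_shadow_mask,
    kmeanspp_cluster,
    select_shadow_cluster,
    select_vegetation_cluster,
)
from shadowcwsi.synthetic import SceneSpec, generate_scene
from .conftest import iou


def brute_force_wcss(x: np.ndarray, k: int) -> float:
    """Global minimum within-cluster sum of squares by full enumeration."""
    n = len(x)
    assignments = np.array(list(itertools.product(range(k), repeat=n)),
                           dtype=np.int8)
    x = np.asarray(x, float)
    wcss = np.zeros(len(assignments))
    for j in range(k):
        members = assignments == j
        cnt = members.sum(axis=1)
        s = members @ x
        ss = members @ (x ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = ss - np.where(cnt > 0, s ** 2 / np.maximum(cnt, 1), 0.0)
        wcss += contrib
    return float(wcss.min())


class TestKmeans:
    def test_two_well_separated_values(self):
        band = np.array([[0, 0, 0], [10, 10, 10]], float)
        model = kmeanspp_cluster(band, k=2, seed=0)
        np.testing.assert_allclose(model.centroids, [0, 10])
        assert (model.labels[0] == 0).all() and (model.labels[1] == 1).all()

    def test_planted_five_blobs(self):
        rng = np.random.default_rng(0)
        means = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
        truth = rng.integers(0, 5, (60, 60))
        band = means[truth] + rng.normal(0, 0.05, (60, 60))
        model = kmeanspp_cluster(band, k=5, seed=0)
        assert (model.labels == truth).mean() >= 0.99
        np.testing.assert_allclose(model.centroids, means, atol=0.05)

    def test_constant_image_rejected(self):
        with pytest.raises(ValidationError, match="distinct"):
            kmeanspp_cluster(np.ones((10, 10)), k=5)

    def test_centroids_sorted_ascending(self):
        rng = np.random.default_rng(3)
        model = kmeanspp_cluster(rng.random((30, 30)), k=5, seed=4)
        assert (np.diff(model.centroids) >= 0).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        band = rng.random((50, 50))
        m1 = kmeanspp_cluster(band, k=5, seed=7)
        m2 = kmeanspp_cluster(band, k=5, seed=7)
        np.testing.assert_array_equal(m1.labels, m2.labels)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_labels_are_fixed_point_of_lloyd_update(self):
        rng = np.random.default_rng(1)
        band = rng.random((20, 20))
        model = kmeanspp_cluster(band, k=3, seed=0)
        # nearest-centroid reassignment must not change any label
        d = np.abs(band[..., None] - model.centroids[None, None, :])
        np.testing.assert_array_equal(d.argmin(axis=2), model.labels)

    @pytest.mark.parametrize("n,k,seed", [
        (8, 2, 0), (10, 3, 1), (12, 3, 2), (12, 3, 3), (9, 3, 4),
    ])
    def test_matches_brute_force_global_optimum(self, n, k, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(n)
        model = kmeanspp_cluster(x.reshape(1, n), k=k, seed=0)
        assert model.inertia == pytest.approx(brute_force_wcss(x, k),
                                              abs=1e-9)

    def test_nodata_pixels_excluded(self):
        band = np.array([[0.0, 1.0, 2.0], [3.0, 4.0, 99.0]])
        valid = band < 50
        model = kmeanspp_cluster(band, k=2, valid=valid)
        assert model.labels[1, 2] == -1
        assert model.centroids.max() < 50


class TestClusterRoles:
    def test_darkest_cluster_is_shadow(self):
        band = np.repeat([0.02, 0.10, 0.25, 0.40, 0.60], 20).reshape(4, 25)
        model = kmeanspp_cluster(band, k=5, seed=0)
        idx = select_shadow_cluster(model)
        assert model.centroids[idx] == pytest.approx(0.02, abs=0.01)

    def test_override_honored(self):
        band = np.repeat([0.0, 1.0, 2.0, 3.0, 4.0], 5).reshape(5, 5)
        model = kmeanspp_cluster(band, k=5, seed=0)
        assert select_shadow_cluster(model, override=3) == 3
        assert select_vegetation_cluster(model, override=2) == 2
        with pytest.raises(ValidationError):
            select_shadow_cluster(model, override=9)

    def test_vegetation_darkest_at_680(self, scene, scene_mask):
        model = kmeanspp_cluster(scene.ms.band("680"), k=5, seed=0)
        veg = select_vegetation_cluster(model, "680")
        assert veg == 0
        assert iou(model.labels == veg, scene.truth.canopy) >= 0.9

    def test_shadow_cluster_overlaps_truth(self, scene):
        model = kmeanspp_cluster(scene.ms.band("490"), k=5, seed=0)
        shadow = model.labels == select_shadow_cluster(model)
        # the darkest 490 nm cluster captures shadow (ground and/or internal)
        assert (shadow & scene.truth.shadow).sum() / shadow.sum() >= 0.9


class TestMaskConstruction:
    def test_internal_subset_of_canopy(self, scene_mask):
        assert not (scene_mask.internal_shadow & ~scene_mask.canopy).any()

    def test_internal_shadow_iou(self, scene, scene_mask):
        assert iou(scene_mask.internal_shadow,
                   scene.truth.internal_shadow) >= 0.9

    def test_shaded_canopy_fraction_recovered(self, scene, scene_mask):
        est = scene_mask.internal_shadow.sum() / scene_mask.canopy.sum()
        true = (scene.truth.internal_shadow.sum()
                / scene.truth.canopy.sum())
        assert est == pytest.approx(true, abs=0.05)

    def test_no_internal_shadow_scene_gives_empty_layer(self):
        sc = generate_scene(SceneSpec(seed=3, shape=(256, 256),
                                      thermal_shape=(110, 110),
                                      internal_shadow_fraction=0.0))
        mask = build_canopy_internal_shadow_mask(sc.ms, seed=0)
        frac = mask.internal_shadow.sum() / max(mask.canopy.sum(), 1)
        assert frac < 0.02

    def test_missing_band_rejected(self):
        img = MultibandImage(np.random.default_rng(0).random((8, 8, 2)),
                             ["490", "550"])
        with pytest.raises(ValidationError, match="680"):
            build_canopy_internal_shadow_mask(img)

    def test_deterministic(self, scene):
        m1 = build_canopy_internal_shadow_mask(scene.ms, seed=0)
        m2 = build_canopy_internal_shadow_mask(scene.ms, seed=0)
        np.testing.assert_array_equal(m1.internal_shadow, m2.internal_shadow)
        np.testing.assert_array_equal(m1.shadow, m2.shadow)
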