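"""Per-band K-means++ segmentation and canopy / internal-shadow masking.

Shadow the canopy casts on itself is invisible in thermal imagery (an
uncooled microbolometer cannot resolve the subtle temperature drop), but it
is dark in the blue band.  Segmentation therefore runs on the multispectral
frame: each band is clustered on its own intensities into five classes
(bare soil, grassy soil, sunlit canopy, ground shadow, internal shadow are
the surface types a vineyard scene presents), and cluster roles are read off
the sorted centroids — the darkest cluster at 680 nm is vegetation (strong
red absorption regardless of illumination), the darkest at 490 nm is shadow.

The mask is built in two stages: (1) cluster the 680 nm band and take the
vegetation cluster as the canopy mask, internal shadow included; (2)
re-cluster the 490 nm intensities of canopy pixels only, splitting them into
sunlit canopy versus internal shadow.  The internal-shadow layer is a subset
of the canopy layer by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import ValidationError
from .raster_io import MultibandImage

__all__ = [
    "ClusterModel",
    "ShadowMask",
    "kmeanspp_cluster",
    "select_shadow_cluster",
    "select_vegetation_cluster",
    "build_canopy_internal_shadow_mask",
]


@dataclass
class ClusterModel:
    """Fitted per-band k-means model with role-stable cluster indexing.

    Centroids are sorted ascending by intensity and labels remapped to match,
    so cluster 0 is always the darkest — role-selection rules can index
    clusters without caring how the optimizer numbered them.
    """

    k: int
    centroids: np.ndarray         # (k,) ascending
    labels: np.ndarray            # (H, W) int, -1 where invalid
    iterations_run: int
    seed: int
    inertia: float                # within-cluster sum of squares

    @property
    def valid(self) -> np.ndarray:
        return self.labels >= 0


@dataclass
class ShadowMask:
    """Boolean layers of a segmented scene.

    ``internal_shadow`` is within-canopy shadow and is always a subset of
    ``canopy``; ``shadow`` collects every pixel classified as shadow (ground
    shadow and internal shadow); ``valid`` marks pixels that carried data.
    """

    shadow: np.ndarray
    canopy: np.ndarray
    internal_shadow: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        shapes = {a.shape for a in (self.shadow, self.canopy,
                                    self.internal_shadow, self.valid)}
        if len(shapes) != 1:
            raise ValidationError(f"mask layer shapes differ: {shapes}")
        if (self.internal_shadow & ~self.canopy).any():
            raise ValidationError("internal_shadow must be a subset of canopy")

    @property
    def sunlit_canopy(self) -> np.ndarray:
        """Canopy pixels that are not internally shaded — the CWSI support."""
        return self.canopy & ~self.internal_shadow & self.valid


def kmeanspp_cluster(band: np.ndarray, k: int = 5, max_iter: int = 200,
                     seed: int = 0, valid: np.ndarray | None = None,
                     n_init: int = 10, tol: float = 1e-6) -> ClusterModel:
    """K-means++ clustering of a single band's intensities into ``k`` classes.

    Five clusters and a 200-iteration cap are the defaults used for vineyard
    scenes.  Clustering is 1-D (the band's own intensities), deterministic
    given ``seed``, and excludes invalid pixels.  Raises
    :class:`ValidationError` when fewer than ``k`` distinct values exist.
    """
    band = np.asarray(band, float)
    if band.ndim != 2:
        raise ValidationError(f"band must be 2-D, got shape {band.shape}")
    if valid is None:
        valid = np.isfinite(band)
    else:
        valid = np.asarray(valid, bool) & np.isfinite(band)
    x = band[valid].reshape(-1, 1)
    n_distinct = len(np.unique(x))
    if n_distinct < k:
        raise ValidationError(
            f"need >= {k} distinct pixel values, found {n_distinct}"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=max_iter, tol=tol, random_state=seed)
    raw = km.fit_predict(x)
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    remap = np.empty(k, int)
    remap[order] = np.arange(k)
    labels = np.full(band.shape, -1, int)
    labels[valid] = remap[raw]
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_.ravel()[order].copy(),
        labels=labels,
        iterations_run=int(km.n_iter_),
        seed=seed,
        inertia=float(km.inertia_),
    )


def select_shadow_cluster(model: ClusterModel,
                          override: int | None = None) -> int:
    """Shadow cluster of a VIS-band model: the darkest centroid.

    At 490/550 nm shadow (ground and internal alike) is the darkest surface.
    ``override`` substitutes an explicit index, preserving the manual
    visual-inspection pathway.
    """
    if override is not None:
        if not 0 <= override < model.k:
            raise ValidationError(f"cluster index {override} not in [0, {model.k})")
        return override
    return 0


def select_vegetation_cluster(model: ClusterModel, band_label=None,
                              override: int | None = None) -> int:
    """Vegetation cluster at 680 nm: the darkest centroid (red absorption)."""
    if override is not None:
        if not 0 <= override < model.k:
            raise ValidationError(f"cluster index {override} not in [0, {model.k})")
        return override
    return 0


def _split_is_real(x: np.ndarray, labels: np.ndarray) -> bool:
    """BIC test: does a two-component split of 1-D data beat one component?

    Uses the hard-classification likelihood of the k-means split (each
    cluster its own Gaussian, mixture weights = cluster fractions) against a
    single Gaussian.  A forced k=2 split of unimodal noise loses this test,
    so a canopy with no internal shadow yields an empty shadow layer.
    """
    n = len(x)
    var_floor = 1e-12
    var1 = max(float(np.var(x)), var_floor)
    ll1 = -0.5 * n * (np.log(2 * np.pi * var1) + 1.0)
    ll2 = 0.0
    for j in (0, 1):
        xj = x[labels == j]
        nj = len(xj)
        if nj == 0:
            return False
        varj = max(float(np.var(xj)), var_floor)
        ll2 += -0.5 * nj * (np.log(2 * np.pi * varj) + 1.0) + nj * np.log(nj / n)
    bic1 = -2 * ll1 + 2 * np.log(n)
    bic2 = -2 * ll2 + 5 * np.log(n)
    return bic2 < bic1


def build_canopy_internal_shadow_mask(ms: MultibandImage, seed: int = 0,
                                      k: int = 5, max_iter: int = 200
                                      ) -> ShadowMask:
    """Two-stage mask: 680 nm canopy extraction, then within-canopy split.

    Stage 1 clusters the 680 nm band (k clusters) and takes the vegetation
    cluster as the canopy mask; the darkest 490 nm cluster of the full frame
    is kept as the ground-shadow component.  Stage 2 re-clusters the 490 nm
    intensities restricted to canopy pixels with k=2 and calls the darker
    sub-cluster internal shadow.
    """
    for needed in ("680", "490"):
        if needed not in ms.band_labels:
            raise ValidationError(
                f"mask construction needs a {needed} nm band; "
                f"have {ms.band_labels}"
            )
    valid = ms.valid
    red = ms.band("680")
    blue = ms.band("490")

    stage1_red = kmeanspp_cluster(red, k=k, max_iter=max_iter, seed=seed,
                                  valid=valid)
    canopy = stage1_red.labels == select_vegetation_cluster(stage1_red, "680")

    stage1_blue = kmeanspp_cluster(blue, k=k, max_iter=max_iter, seed=seed,
                                   valid=valid)
    ground_shadow = stage1_blue.labels == select_shadow_cluster(stage1_blue)

    internal = np.zeros_like(canopy)
    n_canopy = int(canopy.sum())
    if n_canopy:
        distinct = len(np.unique(blue[canopy]))
        if distinct >= 2:
            stage2 = kmeanspp_cluster(blue, k=2, max_iter=max_iter,
                                      seed=seed, valid=canopy)
            if _split_is_real(blue[canopy], stage2.labels[canopy]):
                internal = stage2.labels == 0  # darker sub-cluster
    return ShadowMask(
        shadow=ground_shadow | internal,
        canopy=canopy,
        internal_shadow=internal,
        valid=valid,
    )
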