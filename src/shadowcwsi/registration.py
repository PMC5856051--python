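"""Thermal-multispectral keypoint registration with slope-mode match filtering.

The cross-sensor registration problem: a thermal frame and a multispectral
frame of the same canopy look radically different (temperature vs reflectance,
half the resolution), so a fraction of SIFT matches between them are wrong.
The classical fix, RANSAC, is stochastic and can return different inlier sets
on different runs.  The filter implemented here is deterministic instead:
draw the two frames side by side on one canvas, join every matched pair with
a segment, and compute that segment's slope

    m = (y_tir - y_ms) / ((x_tir + canvas_offset) - x_ms)

where ``canvas_offset`` is the width of the multispectral frame.  Correct
matches between frames related by a (residual) translation all share one
slope, so the histogram mode of the slopes identifies them; pairs whose slope
strays from the mode are rejected.  The kept set feeds a least-squares planar
transform used to pull masks from the multispectral grid onto the thermal one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import exposure, transform as sktransform
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac as sk_ransac

from .errors import (
    DegenerateGeometryError,
    InsufficientMatchesError,
    NoConsensusError,
    ValidationError,
)

__all__ = [
    "MatchSet",
    "SlopeStats",
    "PlanarTransform",
    "detect_and_match",
    "compute_slopes",
    "slope_mode_filter",
    "ransac_filter",
    "estimate_transform",
    "warp_mask",
    "register_pair",
]

_MIN_SAMPLES = {"translation": 1, "similarity": 2, "affine": 3, "homography": 4}
_SK_MODELS = {
    "similarity": sktransform.SimilarityTransform,
    "affine": sktransform.AffineTransform,
    "homography": sktransform.ProjectiveTransform,
}


@dataclass
class MatchSet:
    """Paired keypoints between image A (multispectral) and B (thermal).

    Coordinates are ``(x, y)`` in each image's own pixel grid; the slope of
    pair *i* is evaluated on the side-by-side canvas where image B is drawn
    ``canvas_offset`` pixels to the right of image A's origin.
    """

    pts_a: np.ndarray  # (N, 2) float, (x, y) in image A
    pts_b: np.ndarray  # (N, 2) float, (x, y) in image B
    canvas_offset: float
    slopes: np.ndarray | None = None  # (N,) float, inf = vertical pair
    inlier: np.ndarray | None = None  # (N,) bool

    def __post_init__(self):
        self.pts_a = np.atleast_2d(np.asarray(self.pts_a, float))
        self.pts_b = np.atleast_2d(np.asarray(self.pts_b, float))
        if self.pts_a.shape != self.pts_b.shape or self.pts_a.shape[1] != 2:
            raise ValidationError(
                f"point arrays must both be (N, 2); got {self.pts_a.shape} "
                f"and {self.pts_b.shape}"
            )
        n = len(self.pts_a)
        if self.inlier is None:
            self.inlier = np.ones(n, bool)
        else:
            self.inlier = np.asarray(self.inlier, bool)
        if self.slopes is not None:
            self.slopes = np.asarray(self.slopes, float)
            if len(self.slopes) != n:
                raise ValidationError("slopes length mismatch")
        if len(self.inlier) != n:
            raise ValidationError("inlier length mismatch")

    def __len__(self) -> int:
        return len(self.pts_a)

    @property
    def n_inliers(self) -> int:
        return int(self.inlier.sum())


@dataclass
class SlopeStats:
    """Summary statistics of the pre-filter finite slopes."""

    mode: float
    mean: float
    standard_deviation: float
    max: float
    min: float
    median: float
    bin_width: float


@dataclass
class PlanarTransform:
    """3x3 matrix mapping thermal ``(x, y, 1)`` to multispectral coordinates."""

    model: str
    matrix: np.ndarray
    residual_rms: float = float("nan")

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float).reshape(3, 3)
        if not np.isfinite(self.matrix).all():
            raise DegenerateGeometryError("transform matrix has non-finite entries")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise DegenerateGeometryError("transform matrix is singular")

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        """Map (N, 2) thermal (x, y) points into multispectral coordinates."""
        pts = np.atleast_2d(np.asarray(pts, float))
        h = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return h[:, :2] / h[:, 2:3]

    def inverse(self) -> "PlanarTransform":
        return PlanarTransform(self.model, np.linalg.inv(self.matrix),
                               self.residual_rms)


def _normalize_band(band: np.ndarray) -> np.ndarray:
    """Robust contrast stretch to [0, 1] with adaptive equalization.

    TIR and VIS bands live on incommensurate scales; detection operates on a
    rank-preserving normalization so descriptor gradients are comparable.
    """
    band = np.asarray(band, float)
    lo, hi = np.nanpercentile(band, [1.0, 99.0])
    if hi <= lo:
        return np.zeros_like(band)
    clipped = np.clip((band - lo) / (hi - lo), 0.0, 1.0)
    return exposure.equalize_adapthist(clipped, clip_limit=0.02)


def detect_and_match(band_a: np.ndarray, band_b: np.ndarray,
                     ratio: float = 0.8) -> MatchSet:
    """SIFT keypoints in both bands, mutual nearest-neighbour + ratio matching.

    Returns putative matches (all flagged inlier) with slopes already
    computed on the side-by-side canvas (``canvas_offset`` = width of A).
    Raises :class:`InsufficientMatchesError` below 3 matches.
    """
    if not (0 < ratio <= 1):
        raise ValidationError(f"ratio must be in (0, 1], got {ratio}")
    a = _normalize_band(band_a)
    b = _normalize_band(band_b)
    det_a, det_b = SIFT(), SIFT()
    try:
        det_a.detect_and_extract(a)
        det_b.detect_and_extract(b)
    except RuntimeError as exc:  # skimage raises when no keypoints survive
        raise InsufficientMatchesError(0) from exc
    pairs = match_descriptors(det_a.descriptors, det_b.descriptors,
                              cross_check=True, max_ratio=ratio)
    if len(pairs) < 3:
        raise InsufficientMatchesError(len(pairs))
    # skimage keypoints are (row, col); convert to (x, y)
    pts_a = det_a.keypoints[pairs[:, 0]][:, ::-1].astype(float)
    pts_b = det_b.keypoints[pairs[:, 1]][:, ::-1].astype(float)
    matches = MatchSet(pts_a, pts_b, canvas_offset=float(band_a.shape[1]))
    return compute_slopes(matches)


def compute_slopes(matches: MatchSet) -> MatchSet:
    """Populate per-pair canvas slopes; vertical pairs get an inf sentinel."""
    dy = matches.pts_b[:, 1] - matches.pts_a[:, 1]
    dx = (matches.pts_b[:, 0] + matches.canvas_offset) - matches.pts_a[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(dx == 0, np.inf, dy / np.where(dx == 0, 1.0, dx))
    return replace(matches, slopes=slopes)


def slope_mode_filter(matches: MatchSet, bin_width: float = 0.02,
                      tolerance: float | None = None
                      ) -> tuple[MatchSet, SlopeStats]:
    """Keep matches whose slope agrees with the histogram mode of all slopes.

    The mode of continuous slopes is defined by a histogram of the finite
    slopes with bins of ``bin_width``; the mode is the fullest bin's center,
    ties broken toward the bin nearest the median.  Pairs whose slope differs
    from the mode by more than ``tolerance`` (default ``2 * bin_width``) are
    flagged out, as are infinite-slope (vertical) pairs.  Deterministic:
    identical inputs always produce identical flags.
    """
    if matches.slopes is None:
        matches = compute_slopes(matches)
    if tolerance is None:
        tolerance = 2.0 * bin_width
    slopes = matches.slopes
    finite = np.isfinite(slopes)
    fs = slopes[finite]
    if len(fs) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 finite slopes, have {len(fs)}"
        )
    lo, hi = fs.min(), fs.max()
    if hi == lo:
        mode = float(lo)
    else:
        # sparse binning: occupied bins only, so arbitrarily spread slopes
        # never materialize an enormous histogram
        idx = np.floor((fs - lo) / bin_width)
        occupied, counts = np.unique(idx, return_counts=True)
        med = np.median(fs)
        tied = occupied[counts == counts.max()]
        centers = lo + (tied + 0.5) * bin_width
        mode = float(centers[np.argmin(np.abs(centers - med))])
    stats = SlopeStats(
        mode=mode,
        mean=float(fs.mean()),
        standard_deviation=float(fs.std(ddof=0)),
        max=float(fs.max()),
        min=float(fs.min()),
        median=float(np.median(fs)),
        bin_width=float(bin_width),
    )
    keep = finite & (np.abs(slopes - mode) <= tolerance) & matches.inlier
    return replace(matches, inlier=keep), stats


def _fit_model(model: str, src: np.ndarray, dst: np.ndarray):
    """Least-squares fit of a named transform family, src -> dst."""
    if model == "translation":
        t = sktransform.SimilarityTransform(
            translation=(dst - src).mean(axis=0))
        return t
    tf_cls = _SK_MODELS.get(model)
    if tf_cls is None:
        raise ValidationError(f"unknown transform model {model!r}")
    if model in ("affine", "homography"):
        centered = src - src.mean(axis=0)
        spread = np.linalg.norm(centered, axis=1).max()
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(spread, 1.0)) < 2:
            raise DegenerateGeometryError("source points are collinear")
    tf = tf_cls.from_estimate(src, dst)
    if not tf or not np.isfinite(tf.params).all():
        raise DegenerateGeometryError(
            f"degenerate point configuration for {model} fit"
        )
    return tf


def ransac_filter(matches: MatchSet, model: str = "similarity",
                  threshold: float = 2.0, max_iter: int = 1000,
                  seed: int = 0) -> MatchSet:
    """RANSAC baseline filter: consensus inliers of a fitted transform.

    Stochastic by nature — included as the comparison baseline the slope
    filter replaces; results can differ across seeds on borderline data.
    """
    min_samples = _MIN_SAMPLES.get(model)
    if min_samples is None:
        raise ValidationError(f"unknown transform model {model!r}")
    min_samples = max(min_samples, 2)
    if len(matches) < min_samples:
        raise NoConsensusError(
            f"{len(matches)} matches < minimal sample {min_samples}"
        )
    tf_cls = _SK_MODELS.get(model, sktransform.SimilarityTransform)
    try:
        _, inliers = sk_ransac(
            (matches.pts_a, matches.pts_b),
            tf_cls,
            min_samples=min_samples,
            residual_threshold=threshold,
            max_trials=max_iter,
            rng=seed,
        )
    except Exception as exc:
        raise NoConsensusError(str(exc)) from exc
    if inliers is None or inliers.sum() < min_samples:
        raise NoConsensusError("no consensus set of minimal size")
    return replace(matches, inlier=np.asarray(inliers, bool))


def estimate_transform(matches: MatchSet, model: str = "similarity"
                       ) -> PlanarTransform:
    """Least-squares planar transform over inlier matches (B -> A direction).

    The fitted map takes thermal (image B) pixel coordinates into
    multispectral (image A) coordinates.  Residual RMS is reported in
    image-A pixels.
    """
    n_min = _MIN_SAMPLES.get(model)
    if n_min is None:
        raise ValidationError(f"unknown transform model {model!r}")
    src = matches.pts_b[matches.inlier]
    dst = matches.pts_a[matches.inlier]
    if len(src) < n_min:
        raise DegenerateGeometryError(
            f"{len(src)} inliers < minimal sample {n_min} for {model}"
        )
    tf = _fit_model(model, src, dst)
    resid = np.linalg.norm(tf(src) - dst, axis=1)
    return PlanarTransform(model, tf.params,
                           residual_rms=float(np.sqrt((resid ** 2).mean())))


def warp_mask(mask: np.ndarray, t: PlanarTransform,
              target_shape: tuple[int, int]
              ) -> tuple[np.ndarray, np.ndarray]:
    """Pull a multispectral-grid boolean raster onto the thermal grid.

    ``t`` maps thermal coordinates to multispectral coordinates; every
    thermal pixel center is mapped and the mask sampled nearest-neighbour.
    Returns ``(warped, valid)`` where ``valid`` marks thermal pixels whose
    mapped location fell inside the source frame (out-of-frame pixels are
    invalid, not False).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {mask.shape}")
    h, w = target_shape
    yy, xx = np.mgrid[0:h, 0:w]
    src = t(np.column_stack([xx.ravel(), yy.ravel()]))
    sx, sy = src[:, 0], src[:, 1]
    inside = (sx >= -0.5) & (sx <= mask.shape[1] - 0.5) & \
             (sy >= -0.5) & (sy <= mask.shape[0] - 0.5)
    warped = ndimage.map_coordinates(
        mask.astype(np.uint8), [sy, sx], order=0, mode="constant", cval=0
    ).astype(bool)
    return warped.reshape(h, w), inside.reshape(h, w)


def _phase_refine(t: PlanarTransform, ms_band: np.ndarray,
                  tir_band: np.ndarray) -> PlanarTransform:
    """Subpixel translation correction by phase correlation.

    Renders the thermal frame onto the multispectral grid with the current
    estimate and phase-correlates the two normalized frames; the residual
    shift (bounded to 2 px — anything larger means the correlation locked
    onto the wrong structure and is ignored) is composed into the transform.
    Deterministic.
    """
    from skimage.registration import phase_cross_correlation

    inv = np.linalg.inv(t.matrix)

    def _map(xy):
        h = np.column_stack([xy, np.ones(len(xy))]) @ inv.T
        return h[:, :2] / h[:, 2:3]

    tir_on_ms = sktransform.warp(_normalize_band(tir_band), _map,
                                 output_shape=ms_band.shape, order=1,
                                 cval=np.nan)
    valid = np.isfinite(tir_on_ms)
    a = np.where(valid, _normalize_band(ms_band), 0.0)
    b = np.where(valid, tir_on_ms, 0.0)
    try:
        shift, _, _ = phase_cross_correlation(a, b, upsample_factor=20,
                                              normalization="phase")
    except Exception:
        return t
    dy, dx = float(shift[0]), float(shift[1])
    if not (abs(dx) <= 2.0 and abs(dy) <= 2.0):
        return t
    corr = np.array([[1.0, 0.0, dx], [0.0, 1.0, dy], [0.0, 0.0, 1.0]])
    return PlanarTransform(t.model, corr @ t.matrix, t.residual_rms)


def register_pair(ms_band: np.ndarray, tir_band: np.ndarray, *,
                  ratio: float = 0.8, bin_width: float = 0.02,
                  tolerance: float | None = None, model: str = "similarity",
                  upsample: float = 2.0, trim_px: float = 2.0,
                  refine: bool = True
                  ) -> tuple[PlanarTransform, MatchSet, SlopeStats]:
    """End-to-end slope-filtered registration of a thermal band to a MS band.

    The thermal frame is upsampled (default x2, the resolution ratio of a
    640-px thermal sensor against a 1280-px multispectral camera) before
    detection so that correct matches share a single slope cluster; the
    returned transform composes that upsampling, i.e. maps *original*
    thermal pixel coordinates to multispectral coordinates.

    The slope filter cannot reject a wrong match that happens to lie
    parallel to the correct ones, so the least-squares fit is followed by a
    deterministic residual trim (drop matches with residual > ``trim_px``
    multispectral pixels, refit, repeated to a fixed point).
    """
    tir_up = tir_band if upsample == 1.0 else sktransform.rescale(
        np.asarray(tir_band, float), upsample, order=1, anti_aliasing=False
    )
    matches = detect_and_match(ms_band, tir_up, ratio=ratio)
    filtered, stats = slope_mode_filter(matches, bin_width=bin_width,
                                        tolerance=tolerance)
    if filtered.n_inliers < _MIN_SAMPLES[model]:
        raise InsufficientMatchesError(filtered.n_inliers,
                                       _MIN_SAMPLES[model])
    # robust start: slope-kept matches of a near-translation pair share the
    # full displacement vector, so trim against the median displacement
    # before trusting least squares
    disp = filtered.pts_a - filtered.pts_b
    med = np.median(disp[filtered.inlier], axis=0)
    near = np.linalg.norm(disp - med, axis=1) <= max(trim_px, 2.0)
    if (filtered.inlier & near).sum() >= _MIN_SAMPLES[model]:
        filtered = replace(filtered, inlier=filtered.inlier & near)
    t_up = estimate_transform(filtered, model=model)
    for _ in range(10):
        resid = np.linalg.norm(
            t_up(filtered.pts_b) - filtered.pts_a, axis=1)
        keep = filtered.inlier & (resid <= trim_px)
        if keep.sum() < _MIN_SAMPLES[model] or (keep == filtered.inlier).all():
            break
        filtered = replace(filtered, inlier=keep)
        t_up = estimate_transform(filtered, model=model)
    # pixel-center convention of rescale: x_up = s*x + (s-1)/2
    off = (upsample - 1.0) / 2.0
    scale = np.array([[upsample, 0.0, off], [0.0, upsample, off], [0.0, 0.0, 1.0]])
    full = PlanarTransform(model, t_up.matrix @ scale, t_up.residual_rms)
    if refine:
        full = _phase_refine(full, ms_band, tir_band)
    return full, filtered, stats
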