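"""Synthetic vineyard scenes with known geometry, shadow truth and SWP.

No imagery from the original field campaigns is deposited anywhere, so every
pipeline stage is exercised against rendered scenes instead: east-west
canopy rows on soil (vertical-shoot-positioned training), five surface
classes (bare soil, grassy soil, sunlit canopy, canopy-cast ground shadow,
internal within-canopy shadow) rendered consistently in six VIS/NIR bands
and one thermal band.  The thermal frame sits on its own half-resolution
grid related to the multispectral grid by a known similarity transform, so
registration can be scored against truth.

Scene composition defaults follow the study vineyard: 19% fractional
cover and 43% of canopy pixels internally shaded.  Per-vine stem water
potential is drawn from the two irrigation treatments (well-watered
-0.6..-0.8 MPa, deficit -0.9..-1.25 MPa) and sunlit canopy temperature is
coupled linearly to SWP, so true CWSI correlates with SWP by construction;
internal shadow is cooler than sunlit canopy by a per-vine random offset,
planting the contamination that shadow filtering is meant to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .raster_io import MultibandImage, VineRecord
from .registration import MatchSet, PlanarTransform, compute_slopes
from .segmentation import ShadowMask

__all__ = ["SceneSpec", "Scene", "generate_scene", "generate_match_fixture",
           "BAND_LABELS", "CLASS_NAMES"]

BAND_LABELS = ["490", "550", "680", "720", "800", "900"]

# surface classes
BARE, GRASS, CANOPY, GROUND_SHADOW, INTERNAL_SHADOW = range(5)
CLASS_NAMES = ["bare_soil", "grassy_soil", "sunlit_canopy",
               "ground_shadow", "internal_shadow"]

# mean reflectance per class per band (490..900 nm).  Encodes the contrast
# ordering that makes 490 nm the discriminative shadow band (shadows darkest
# in blue) and 680 nm the canopy band (red absorbed by vegetation whether
# sunlit or shaded, soils bright).
_DEFAULT_REFLECTANCE = {
    BARE:            [0.180, 0.220, 0.300, 0.320, 0.340, 0.360],
    GRASS:           [0.120, 0.160, 0.200, 0.240, 0.300, 0.320],
    CANOPY:          [0.080, 0.100, 0.050, 0.280, 0.460, 0.480],
    GROUND_SHADOW:   [0.020, 0.040, 0.110, 0.090, 0.110, 0.120],
    INTERNAL_SHADOW: [0.030, 0.050, 0.042, 0.160, 0.240, 0.250],
}

# surface temperature means, deg C, for the non-canopy classes
_DEFAULT_TEMPS = {BARE: 45.0, GRASS: 38.0, GROUND_SHADOW: 30.0}


@dataclass
class SceneSpec:
    """Parameters of a rendered vineyard scene.

    ``fractional_cover`` is the canopy fraction of ground area;
    ``internal_shadow_fraction`` the shaded fraction of canopy pixels.
    Sunlit canopy temperature is ``t_canopy_base - swp_gain * SWP`` (SWP
    negative, so stressed vines are warmer); internal shadow is cooler by a
    per-vine offset ~ N(shade_cooling_mean, shade_cooling_sd), floored at
    shade_cooling_min.
    """

    shape: tuple[int, int] = (512, 512)
    thermal_shape: tuple[int, int] = (236, 236)
    rows: int = 8
    row_orientation: float = 0.0          # degrees from east-west
    vines_per_row: int = 4
    fractional_cover: float = 0.19
    internal_shadow_fraction: float = 0.43
    ground_shadow_fraction: float = 0.12  # of the row pitch
    grass_fraction: float = 0.20          # of the whole frame
    reflectance: dict = field(default_factory=lambda: dict(_DEFAULT_REFLECTANCE))
    reflectance_noise_sd: float = 0.012
    soil_temps: dict = field(default_factory=lambda: dict(_DEFAULT_TEMPS))
    t_canopy_base: float = 24.0
    swp_gain: float = 6.0                 # deg C per MPa
    canopy_temp_jitter_sd: float = 0.5    # per-vine scatter around coupling
    shade_cooling_mean: float = 4.0
    shade_cooling_sd: float = 1.5
    shade_cooling_min: float = 1.5
    temp_noise_sd: float = 0.35
    swp_well_watered: tuple[float, float] = (-0.80, -0.60)
    swp_deficit: tuple[float, float] = (-1.25, -0.90)
    shade_fraction_jitter: float = 0.06   # per-vine spread of shaded fraction
    transform_scale: float = 2.0
    transform_translation: tuple[float, float] = (18.0, 11.0)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.fractional_cover < 1:
            raise ValidationError(
                f"fractional_cover must be in (0,1), got {self.fractional_cover}")
        if not 0 <= self.internal_shadow_fraction < 1:
            raise ValidationError(
                "internal_shadow_fraction must be in [0,1), got "
                f"{self.internal_shadow_fraction}")
        if self.rows < 1 or self.vines_per_row < 1:
            raise ValidationError("need at least one row and one vine per row")
        if self.shade_cooling_min <= 0:
            raise ValidationError("internal shadow must be cooler than sunlit "
                                  "canopy (shade_cooling_min > 0)")
        s, (dx, dy) = self.transform_scale, self.transform_translation
        ht, wt = self.thermal_shape
        h, w = self.shape
        if not (0 <= dx and s * (wt - 1) + dx < w and
                0 <= dy and s * (ht - 1) + dy < h):
            raise ValidationError("thermal footprint falls outside the "
                                  "multispectral frame")

    @property
    def true_transform(self) -> PlanarTransform:
        s, (dx, dy) = self.transform_scale, self.transform_translation
        return PlanarTransform(
            "similarity", [[s, 0.0, dx], [0.0, s, dy], [0.0, 0.0, 1.0]])


@dataclass
class Scene:
    """A rendered scene with every ground-truth layer the pipeline can use."""

    ms: MultibandImage
    thermal: MultibandImage
    truth: ShadowMask                # multispectral grid
    truth_thermal: ShadowMask        # thermal grid
    zones: np.ndarray                # thermal-grid vine labels (0 = none)
    zones_ms: np.ndarray             # multispectral-grid vine labels
    vines: list[VineRecord]
    true_transform: PlanarTransform
    class_map: np.ndarray            # multispectral-grid class indices
    temperature: np.ndarray          # noise-free temperature, MS grid


def _smooth_noise(rng, shape, sigma):
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return g / max(g.std(), 1e-12)


def generate_scene(spec: SceneSpec | None = None) -> Scene:
    """Render a vineyard scene; deterministic given ``spec.seed``."""
    spec = spec or SceneSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    theta = np.deg2rad(spec.row_orientation)
    v = xx * np.sin(theta) + yy * np.cos(theta)   # across-row coordinate
    u = xx * np.cos(theta) - yy * np.sin(theta)   # along-row coordinate

    pitch = h / spec.rows
    # integer stripe thickness, rounded so the realized class fraction is
    # unbiased on the pixel grid
    h_canopy = max(1.0, np.round(spec.fractional_cover * pitch))
    h_gshadow = spec.ground_shadow_fraction * pitch
    phase = np.mod(v, pitch)
    row_index = np.floor(v / pitch).astype(int) % spec.rows

    class_map = np.full((h, w), BARE, int)
    grass_field = _smooth_noise(rng, (h, w), 16.0)
    class_map[grass_field > np.quantile(grass_field,
                                        1.0 - spec.grass_fraction)] = GRASS

    canopy = phase < h_canopy
    gshadow = (phase >= h_canopy) & (phase < h_canopy + h_gshadow)
    class_map[gshadow] = GROUND_SHADOW
    class_map[canopy] = CANOPY

    # vine zones: split each row's canopy along u
    vine_along = np.clip((u / (w / spec.vines_per_row)).astype(int),
                         0, spec.vines_per_row - 1)
    zone_id = row_index * spec.vines_per_row + vine_along + 1
    zones_ms = np.where(canopy, zone_id, 0)

    n_vines = spec.rows * spec.vines_per_row
    treatments = np.tile([0, 1], n_vines)[:n_vines]  # alternate WW / deficit
    lo_ww, hi_ww = spec.swp_well_watered
    lo_d, hi_d = spec.swp_deficit
    swp = np.where(treatments == 0,
                   rng.uniform(lo_ww, hi_ww, n_vines),
                   rng.uniform(lo_d, hi_d, n_vines))
    vines = [VineRecord(f"vine{z:02d}", z, float(swp[z - 1]))
             for z in range(1, n_vines + 1)]

    # internal shadow: contiguous blobs on the row's shaded side
    shade_frac = np.clip(
        spec.internal_shadow_fraction
        + rng.uniform(-spec.shade_fraction_jitter,
                      spec.shade_fraction_jitter, n_vines),
        0.0, 0.95)
    if spec.internal_shadow_fraction == 0:
        shade_frac[:] = 0.0
    blob = _smooth_noise(rng, (h, w), 6.0)
    # shade score: large on the row's lower (shaded) side, modulated by a
    # smooth blob field so boundaries are contiguous, not salt-and-pepper;
    # the per-vine threshold is the score quantile that realizes the
    # requested shaded fraction of that vine's canopy pixels
    score = phase + 0.22 * h_canopy * blob
    internal = np.zeros((h, w), bool)
    for z in range(1, n_vines + 1):
        fz = shade_frac[z - 1]
        zone_px = zones_ms == z
        if fz <= 0 or not zone_px.any():
            continue
        cut = np.quantile(score[zone_px], 1.0 - fz)
        internal |= zone_px & (score > cut)
    class_map[internal] = INTERNAL_SHADOW

    # reflectance rendering
    refl_table = np.array([spec.reflectance[c] for c in range(5)])
    ms_px = refl_table[class_map] + rng.normal(
        0.0, spec.reflectance_noise_sd, (h, w, 6))
    ms = MultibandImage(np.clip(ms_px, 0.0, 1.0).astype(np.float32),
                        list(BAND_LABELS))

    # temperature field (noise-free), MS grid
    temp = np.empty((h, w))
    for cls, t in spec.soil_temps.items():
        temp[class_map == cls] = t
    t_sunlit_vine = (spec.t_canopy_base - spec.swp_gain * swp
                     + rng.normal(0.0, spec.canopy_temp_jitter_sd, n_vines))
    cooling = np.maximum(
        rng.normal(spec.shade_cooling_mean, spec.shade_cooling_sd, n_vines),
        spec.shade_cooling_min)
    vine_at = np.maximum(zone_id, 1) - 1
    sunlit_t = t_sunlit_vine[vine_at]
    temp[class_map == CANOPY] = sunlit_t[class_map == CANOPY]
    temp[class_map == INTERNAL_SHADOW] = (sunlit_t - cooling[vine_at])[
        class_map == INTERNAL_SHADOW]

    truth = ShadowMask(
        shadow=(class_map == GROUND_SHADOW) | (class_map == INTERNAL_SHADOW),
        canopy=(class_map == CANOPY) | (class_map == INTERNAL_SHADOW),
        internal_shadow=class_map == INTERNAL_SHADOW,
        valid=np.ones((h, w), bool),
    )

    # thermal frame on its own grid, sampled through the true transform
    t_true = spec.true_transform
    ht, wt = spec.thermal_shape
    tyy, txx = np.mgrid[0:ht, 0:wt]
    src = t_true(np.column_stack([txx.ravel(), tyy.ravel()]))
    sx = np.clip(np.round(src[:, 0]).astype(int), 0, w - 1)
    sy = np.clip(np.round(src[:, 1]).astype(int), 0, h - 1)
    thermal_px = temp[sy, sx].reshape(ht, wt) + rng.normal(
        0.0, spec.temp_noise_sd, (ht, wt))
    thermal = MultibandImage(thermal_px.astype(np.float32), ["TIR"])

    cls_t = class_map[sy, sx].reshape(ht, wt)
    truth_thermal = ShadowMask(
        shadow=(cls_t == GROUND_SHADOW) | (cls_t == INTERNAL_SHADOW),
        canopy=(cls_t == CANOPY) | (cls_t == INTERNAL_SHADOW),
        internal_shadow=cls_t == INTERNAL_SHADOW,
        valid=np.ones((ht, wt), bool),
    )
    zones_thermal = zones_ms[sy, sx].reshape(ht, wt)

    return Scene(ms=ms, thermal=thermal, truth=truth,
                 truth_thermal=truth_thermal, zones=zones_thermal,
                 zones_ms=zones_ms, vines=vines, true_transform=t_true,
                 class_map=class_map, temperature=temp)


def generate_match_fixture(n_inliers: int, n_outliers: int = 0,
                           true_shift: tuple[float, float] = (0.0, 0.0),
                           noise_sd: float = 0.0, seed: int = 0,
                           size: tuple[int, int] = (512, 512)
                           ) -> tuple[MatchSet, np.ndarray]:
    """Planted keypoint-match fixture for scoring match filters.

    Inlier pairs are displaced by ``true_shift`` plus Gaussian localization
    noise; outlier pairs land uniformly anywhere on both frames.  Returns
    the match set (slopes populated, canvas offset = frame width) and the
    planted ground-truth inlier labels.
    """
    if n_inliers < 3:
        raise ValidationError(f"need >= 3 inliers, got {n_inliers}")
    rng = np.random.default_rng(seed)
    w, hgt = size
    dx, dy = true_shift
    a_in = np.column_stack([rng.uniform(0, w, n_inliers),
                            rng.uniform(0, hgt, n_inliers)])
    b_in = a_in + [dx, dy] + rng.normal(0, noise_sd, (n_inliers, 2))
    a_out = np.column_stack([rng.uniform(0, w, n_outliers),
                             rng.uniform(0, hgt, n_outliers)])
    b_out = np.column_stack([rng.uniform(0, w, n_outliers),
                             rng.uniform(0, hgt, n_outliers)])
    pts_a = np.vstack([a_in, a_out])
    pts_b = np.vstack([b_in, b_out])
    labels = np.zeros(n_inliers + n_outliers, bool)
    labels[:n_inliers] = True
    matches = compute_slopes(MatchSet(pts_a, pts_b, canvas_offset=float(w)))
    return matches, labels
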