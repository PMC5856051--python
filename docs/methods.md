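# Methods

This note records the models, parameter choices and numerical decisions
behind `shadowcwsi`, and what the synthetic-scene tests do and do not show
about real imagery.

## Slope-mode match filtering

Putative correspondences come from SIFT keypoints (scikit-image) detected
on contrast-normalized bands (1–99 percentile stretch followed by adaptive
histogram equalization, so TIR and reflectance frames are comparable),
matched by mutual nearest neighbour with Lowe's ratio test (default 0.8).

Both frames are treated as one side-by-side canvas: the thermal x
coordinates are offset by the multispectral frame width, and each matched
pair gets the slope `m = Δy/Δx` of the segment joining its two keypoints.
If the frames are related by a pure translation (after resolution
matching), every correct match has the same slope, so the mode of the
slope distribution identifies the correct cluster without any random
sampling — the filter is a deterministic alternative to RANSAC, whose
consensus set can change from run to run on ambiguous cross-modal matches.

A mode of continuous slopes needs discretization. We bin finite slopes
with a fixed width (default 0.02 slope units, anchored at the minimum
slope, occupied bins stored sparsely so unbounded slopes cost nothing) and
take the fullest bin's center, breaking ties toward the bin nearest the
median. Matches farther than a tolerance (default 2 × bin width) from the
mode are dropped, as are vertical pairs (zero canvas Δx, flagged with an
infinite-slope sentinel). An exact-equality test against the mode would
discard everything on continuous data; the tolerance makes the rule
well-defined.

Because the two cameras differ ×2 in resolution (1280 vs 640 px wide),
the thermal frame is bilinearly upsampled ×2 before detection — without
this, correct matches would not share one slope. The returned transform
composes the upsampling (including the half-pixel center offset of the
rescaling) and maps original thermal pixel coordinates to multispectral
coordinates.

Two deterministic refinements follow the filter, both needed because a
wrong match that happens to run parallel to the correct ones passes any
slope test: (1) matches whose displacement vector strays more than 2 px
from the median displacement of the kept set are dropped, then the
least-squares fit is iterated to a fixed point dropping residuals > 2 px;
(2) the fitted transform is polished by phase correlation between the
registered frames (subpixel, capped at ±2 px so a wrong lock is ignored).
The default transform family is similarity (translation + rotation +
scale), adequate for near-nadir fixed-altitude flights; homography is
available by flag.

## Segmentation and the two-stage mask

Each band is clustered on its own 1-D intensities with k-means++
(scikit-learn, 5 clusters, 200-iteration cap, explicit seed, 10
initializations, centroids reported ascending so cluster 0 is always
darkest). Five clusters match the five surface types a vineyard scene
presents: bare soil, grassy soil, sunlit canopy, canopy-cast ground
shadow, internal canopy shadow. Role assignment is automated where the
original workflow used visual inspection: the darkest cluster at 680 nm
is vegetation (chlorophyll absorbs red whether sunlit or shaded), the
darkest at 490 nm is shadow (blue is the discriminative shadow band);
explicit index overrides preserve the manual pathway.

The mask is built in two stages: the 680 nm vegetation cluster gives the
canopy mask (internal shadow included); the 490 nm intensities of canopy
pixels only are then re-split with k = 2 into sunlit canopy vs internal
shadow — two classes being the minimal reading of "vegetation and
internal shaded canopy". A forced k = 2 split of a canopy with *no*
internal shadow would manufacture one from noise, so the split is accepted
only if a two-component (hard-classification Gaussian) model beats a
one-component model by BIC; otherwise the internal-shadow layer is empty.
Nodata pixels are excluded from clustering, histograms and statistics
everywhere via explicit validity masks.

## CWSI

`CWSI = (T − T_wet)/(T_dry − T_wet)` over sunlit-canopy pixels on the
thermal grid. The references are extracted per scene (never pooled across
flights) from the shadow-filtered canopy temperature histogram as
symmetric tail percentiles, default 0.5/99.5 — the stable core of the
adaptive histogram approach; they are indicator temperatures, not
physical extremes, so out-of-range pixels are clipped into [0, 1] and
counted rather than dropped. Non-canopy and shaded pixels are absent
(NaN), never zero. Masks travel from the multispectral grid to the
thermal grid by nearest-neighbour pullback through the fitted transform;
out-of-frame pixels are marked invalid, not shadow-free.

Per-vine zonal means feed an OLS of SWP on CWSI with R², RMSE (n
denominator) and residual standard error (n − 2 denominator), both in
MPa. Zones with fewer than 30 valid pixels (slivers clipped at the
thermal frame edge) are reported but excluded from the regression — a
mean over a handful of contaminated boundary pixels is not an
observation.

## Agreement metrics

Binary confusion matrices (rows observed, columns predicted), the
percentage of correctly classified shadow — precision of the
predicted-shadow column, the only reading arithmetically consistent with
every row of the published benchmark table bundled in
`evaluation.reference_confusion_matrices()` — and Cohen's kappa
κ = (p_o − p_e)/(1 − p_e). Report formatting mirrors that table:
percentages rounded to integers, kappa *truncated* to two decimals (the
bundled table's 0.76 and 0.54 rows are truncations of 0.7663 and 0.5477;
rounding would print 0.77/0.55). Full precision is always available from
the computing functions.

## Synthetic scenes

The generator renders what the algorithms need and no more: east–west
canopy stripes on soil at 19% fractional cover, internal shadow painted
as contiguous blobs on the row's lower side covering 43% of canopy pixels
(both figures are the study vineyard's composition; per-vine shaded
fraction jitters ±6 points, realized exactly per vine by quantile
thresholding of a smoothed score field), a ground-shadow band beside each
row, smooth grass patches, and Gaussian reflectance noise (sd 0.012)
around per-class band means chosen so shadows are darkest at 490 nm and
vegetation darkest at 680 nm — the contrast ordering that makes those the
discriminative bands. The thermal frame lives on its own half-resolution
grid related to the multispectral grid by a known similarity transform
(scale 2, translation ~(18, 11) px).

Temperatures: bare soil 45 °C, grass 38 °C, ground shadow 30 °C; sunlit
canopy `24 − 6·SWP` °C with per-vine scatter (sd 0.5 °C), SWP drawn from
the two irrigation treatments (−0.6…−0.8 and −0.9…−1.25 MPa); internal
shadow cooler than its vine's sunlit canopy by a per-vine offset
N(4, 1.5²) °C floored at 1.5; pixel noise sd 0.35 °C. True CWSI thus
correlates with SWP by construction, and the shade-cooling bias plants
exactly the contamination the filter is meant to remove — the per-vine
product of shaded fraction and cooling offset is noise in the unfiltered
regression and absent from the filtered one.

Scenes default to 512×512 multispectral / 236×236 thermal — large enough
for stable cluster statistics and a few hundred SIFT keypoints, small
enough that the whole pipeline runs in seconds.

What the generator does not emulate: radiative transfer or sun geometry
(shadows are statistical stand-ins), mixed boundary pixels from a real
PSF, mosaicking artifacts, emissivity variation, atmospheric effects, or
cross-modal appearance differences beyond a monotone intensity flip.
Passing tests therefore demonstrate algorithmic correctness and the
direction and mechanism of the shadow effect, not field-calibrated
accuracy; published field regression values are not reproducible without
the original imagery, and the package makes no claim to reproduce them.

## Numerical details and edge cases

- All stochastic components (k-means seeding, RANSAC, scene synthesis)
  take explicit integer seeds; identical inputs and seeds give bitwise
  identical outputs.
- k-means convergence: tolerance 1e-6 or the iteration cap. Fewer than k
  distinct values is an error naming the count.
- Fewer than 3 matches raises an insufficient-matches error carrying the
  count; an all-vertical match set is degenerate geometry; collinear
  points are rejected before affine/homography fits.
- A constant temperature field makes T_wet = T_dry and raises a
  degenerate-histogram error; reference extraction requires ≥ 30 sunlit
  pixels.
- Empty vine zones are data (n = 0, missing mean), not failures.

## Known limitations

- The slope filter assumes the residual transform after resolution
  matching is translation-dominated; strong rotation or perspective would
  spread the correct-match slopes across bins.
- Cluster-role rules assume vegetation darkest at 680 nm and shadow
  darkest at 490 nm; unusual soils or senescent canopies would need the
  manual override pathway.
- Agreement metrics are strictly binary; multi-class kappa is out of
  scope.
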