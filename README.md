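# shadowcwsi

Thermal–multispectral coregistration, canopy shadow removal and Crop Water
Stress Index (CWSI) mapping for UAV vineyard imagery.

## The problem

UAV-borne thermal infrared (TIR) imagery is used to map canopy temperature
and derive the Crop Water Stress Index

```
CWSI = (T_canopy − T_wet) / (T_dry − T_wet)
```

where `T_wet` is the temperature of a fully transpiring canopy and `T_dry`
that of a non-transpiring, fully stressed one (0 = unstressed, 1 = fully
stressed). Per-vine CWSI is then regressed against midday stem water
potential (SWP, MPa) to assess plant water status at scale.

The catch: a vertical canopy wall shades part of itself, and these
*internal shadow* pixels are cooler than sunlit canopy yet invisible to an
uncooled microbolometer — they contaminate `T_canopy` and weaken the
CWSI–SWP relationship. Shadow is, however, obvious in the blue band of a
multispectral camera. This package automates the cross-sensor fix:

1. **Segmentation** — per-band K-means++ (5 clusters, 200 iterations) on
   the multispectral frame; the darkest 680 nm cluster is canopy (strong
   red absorption), and a second k=2 split of the canopy's 490 nm
   intensities separates sunlit canopy from internal shadow.
2. **Coregistration** — SIFT keypoints matched between the thermal frame
   (upsampled ×2 to the multispectral resolution) and a multispectral
   band. Wrong matches are rejected *deterministically* by the slope-mode
   rule: draw both frames side by side, compute each matched pair's slope
   `m = (y′ − y) / ((x′ + offset) − x)` on that canvas, and keep only
   pairs whose slope agrees with the histogram mode — correct matches
   between translation-related frames all share one slope. (A RANSAC
   baseline is included for comparison; unlike the slope filter its output
   is seed-dependent.)
3. **Shadow-filtered CWSI** — the mask is pulled onto the thermal grid
   (temperatures are never resampled), `T_wet`/`T_dry` are taken from the
   0.5th/99.5th percentiles of the shadow-filtered canopy temperature
   histogram, and CWSI is mapped over sunlit canopy only, with per-vine
   zonal means and OLS diagnostics (R², RMSE, SE) against SWP.

Mask accuracy is scored with binary confusion matrices, the percentage of
correctly classified shadow (precision of the predicted-shadow class) and
Cohen's kappa. Since no imagery from the original field campaigns is
publicly deposited, a synthetic scene generator renders row-structured
vineyard scenes (bare soil, grassy soil, sunlit canopy, ground shadow,
internal shadow; six VIS/NIR bands + thermal on its own half-resolution
grid with a known transform) with full ground truth.

## Worked example

Generate a synthetic scene and run the full workflow:

```
$ shadowcwsi synth --seed 1 --out scene
scene written to scene

$ shadowcwsi shadowmask --ms scene/ms.tif --out seg
canopy 18.7% of frame, internal shadow 44.1% of canopy

$ shadowcwsi coreg --thermal scene/thermal.tif --ms scene/ms.tif \
      --ms-band 490 --out reg
25/88 inlier matches; residual RMS 1.031 px
```

The scene was built with 19% fractional cover and 43% of canopy shaded;
segmentation recovers both within about a point. Of 88 putative SIFT
matches the slope filter keeps 25, enough to fit the similarity transform
to ~1 px. The end-to-end run (config in YAML):

```
$ shadowcwsi pipeline --config run.yaml
6/6 stages completed; outputs in run

$ shadowcwsi evaluate --observed scene/truth_mask_thermal.tif \
      --predicted run/shadow_warped.tif --out eval.json
precision 99%, kappa 0.98
```

`run/metrics.json` then holds the headline comparison — the per-vine
CWSI–SWP regression over sunlit canopy: slope −1.01, R² = 0.79,
RMSE = 0.090 MPa, SE = 0.093 MPa (n = 28 vines). Rebuilding the same map
*without* removing internal shadow drops R² to ≈ 0.5 on the same scene:
the cool shade pixels add per-vine noise that the filter removes.

The library mirrors the CLI (`shadowcwsi.run`, `register_pair`,
`build_canopy_internal_shadow_mask`, `compute_cwsi`, ...); see the module
docstrings and `docs/methods.md`.

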