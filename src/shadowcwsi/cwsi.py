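"""Crop Water Stress Index over sunlit canopy pixels.

CWSI = (T_canopy - T_wet) / (T_dry - T_wet), where T_wet is the temperature
of a fully transpiring canopy and T_dry that of a non-transpiring, fully
stressed one.  Neither needs to be an absolute physical limit — they act as
indicator temperatures scaling observed canopy temperature onto [0, 1].
Here both are extracted adaptively from the shadow-filtered canopy
temperature histogram: T_wet from its lowest tail, T_dry from its highest
(symmetric percentiles, 0.5 / 99.5 by default), per scene and never pooled
across flights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateHistogramError, ValidationError
from .raster_io import MultibandImage, VineRecord
from .segmentation import ShadowMask

__all__ = ["CwsiMap", "extract_reference_temps", "compute_cwsi", "zonal_cwsi"]


@dataclass
class CwsiMap:
    """Per-pixel CWSI over sunlit canopy plus the scalars that produced it.

    Non-canopy and internally shaded pixels are NaN (absent), never zero.
    Pixels whose temperature fell outside [t_wet, t_dry] are clipped into
    [0, 1]; ``n_clipped`` counts them.
    """

    cwsi: np.ndarray
    t_wet: float
    t_dry: float
    t_canopy_mean: float
    t_canopy_sd: float
    n_clipped: int = 0

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.cwsi)


def _as_sunlit(mask) -> np.ndarray:
    if isinstance(mask, ShadowMask):
        return mask.sunlit_canopy
    return np.asarray(mask, bool)


def _thermal_band(thermal) -> np.ndarray:
    if isinstance(thermal, MultibandImage):
        if thermal.n_bands != 1:
            raise ValidationError("thermal image must be single-band")
        return thermal.pixels[:, :, 0]
    return np.asarray(thermal, float)


def extract_reference_temps(thermal, sunlit_mask, p_low: float = 0.5,
                            p_high: float = 99.5, min_pixels: int = 30
                            ) -> tuple[float, float]:
    """Adaptive T_wet / T_dry from the sunlit-canopy temperature histogram.

    Returns the ``p_low``-th and ``p_high``-th percentiles of sunlit-canopy
    temperatures.  Requires at least ``min_pixels`` canopy pixels and a
    non-degenerate spread (t_wet < t_dry).
    """
    if not 0 <= p_low < p_high <= 100:
        raise ValidationError(f"bad percentiles ({p_low}, {p_high})")
    t = _thermal_band(thermal)
    sunlit = _as_sunlit(sunlit_mask)
    if sunlit.shape != t.shape:
        raise ValidationError(
            f"mask shape {sunlit.shape} != thermal shape {t.shape}"
        )
    temps = t[sunlit & np.isfinite(t)]
    if len(temps) < min_pixels:
        raise ValidationError(
            f"only {len(temps)} sunlit-canopy pixels, need >= {min_pixels}"
        )
    t_wet, t_dry = np.percentile(temps, [p_low, p_high])
    if not t_wet < t_dry:
        raise DegenerateHistogramError(
            f"degenerate temperature histogram: t_wet == t_dry == {t_wet:g}"
        )
    return float(t_wet), float(t_dry)


def compute_cwsi(thermal, mask, t_wet: float, t_dry: float) -> CwsiMap:
    """Eq. CWSI = (T - t_wet)/(t_dry - t_wet) over sunlit-canopy pixels."""
    if not t_dry > t_wet:
        raise ValidationError(f"t_dry ({t_dry}) must exceed t_wet ({t_wet})")
    t = _thermal_band(thermal)
    sunlit = _as_sunlit(mask)
    if sunlit.shape != t.shape:
        raise ValidationError(
            f"mask shape {sunlit.shape} != thermal shape {t.shape}"
        )
    support = sunlit & np.isfinite(t)
    raw = (t - t_wet) / (t_dry - t_wet)
    cwsi = np.full(t.shape, np.nan)
    cwsi[support] = raw[support]
    n_clipped = int(((cwsi < 0) | (cwsi > 1)).sum())
    np.clip(cwsi, 0.0, 1.0, out=cwsi)
    temps = t[support]
    return CwsiMap(
        cwsi=cwsi,
        t_wet=float(t_wet),
        t_dry=float(t_dry),
        t_canopy_mean=float(temps.mean()) if len(temps) else float("nan"),
        t_canopy_sd=float(temps.std(ddof=0)) if len(temps) else float("nan"),
        n_clipped=n_clipped,
    )


def zonal_cwsi(cwsi_map: CwsiMap, vines: list[VineRecord] | None,
               zones: np.ndarray) -> pd.DataFrame:
    """Per-vine mean CWSI over each zone of a label raster.

    Zones with no valid CWSI pixel are reported with ``n_pixels = 0`` and a
    missing mean — empty zones are data, not failures.  When ``vines`` is
    None every nonzero zone label becomes an anonymous record.
    """
    zones = np.asarray(zones)
    if zones.shape != cwsi_map.cwsi.shape:
        raise ValidationError(
            f"zone raster shape {zones.shape} != CWSI shape {cwsi_map.cwsi.shape}"
        )
    if vines is None:
        vines = [VineRecord(f"zone{z}", int(z))
                 for z in np.unique(zones) if z != 0]
    rows = []
    ok = cwsi_map.valid
    for v in vines:
        sel = (zones == v.zone_label) & ok
        n = int(sel.sum())
        rows.append({
            "vine_id": v.vine_id,
            "mean_cwsi": float(cwsi_map.cwsi[sel].mean()) if n else np.nan,
            "n_pixels": n,
            "swp_mpa": v.swp_mpa if v.swp_mpa is not None else np.nan,
        })
    return pd.DataFrame(rows, columns=["vine_id", "mean_cwsi", "n_pixels",
                                       "swp_mpa"])
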