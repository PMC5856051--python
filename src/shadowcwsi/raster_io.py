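"""Raster and table I/O plus the pixel-coordinate conventions used everywhere.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)`` with the origin at the top-left
  corner.  Keypoints and transforms use ``(x, y) = (col, row)`` floating-point
  coordinates at pixel centers.
* Multiband rasters are stored ``(H, W, B)``; band labels are wavelength tags
  in nanometres (``"490"`` ... ``"900"``) or ``"TIR"`` for the thermal band.
* Reflectance is kept on whatever scale the file carries (typically [0, 1] or
  raw DN); thermal values are degrees Celsius.  Nodata is an explicit validity
  mask, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ValidationError

__all__ = [
    "MultibandImage",
    "VineRecord",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_vine_table",
    "write_vine_table",
]


@dataclass
class MultibandImage:
    """An ``(H, W, B)`` raster with named bands and an optional nodata value."""

    pixels: np.ndarray
    band_labels: list[str]
    nodata_value: float | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ValidationError(f"pixels must be HxW or HxWxB, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1 or px.shape[2] < 1:
            raise ValidationError(f"empty raster: shape {px.shape}")
        self.pixels = px
        self.band_labels = [str(b) for b in self.band_labels]
        if len(self.band_labels) != px.shape[2]:
            raise ValidationError(
                f"{len(self.band_labels)} band labels for {px.shape[2]} bands"
            )
        if len(set(self.band_labels)) != len(self.band_labels):
            raise ValidationError(f"duplicate band labels: {self.band_labels}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[2]

    def band(self, label) -> np.ndarray:
        """Return one band as a 2-D array (a view, not a copy)."""
        label = str(label)
        try:
            idx = self.band_labels.index(label)
        except ValueError:
            raise ValidationError(
                f"band {label!r} not among {self.band_labels}"
            ) from None
        return self.pixels[:, :, idx]

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of pixels valid in *every* band."""
        px = self.pixels
        ok = np.isfinite(px).all(axis=2) if px.dtype.kind == "f" else np.ones(
            px.shape[:2], bool
        )
        if self.nodata_value is not None:
            ok &= ~(px == self.nodata_value).any(axis=2)
        return ok


@dataclass
class VineRecord:
    """One monitored vine: a zone label in the raster and its measured SWP.

    Stem water potential is in MPa and is negative when present (the study
    range spans roughly -0.6 to -1.25 MPa across irrigation treatments).
    """

    vine_id: str
    zone_label: int
    swp_mpa: float | None = None

    def __post_init__(self):
        if self.swp_mpa is not None and not self.swp_mpa < 0:
            raise ValidationError(
                f"vine {self.vine_id}: SWP must be negative, got {self.swp_mpa}"
            )


def read_image(path, band_labels: list | None = None,
               nodata_value: float | None = None) -> MultibandImage:
    """Read a TIFF/GeoTIFF or PNG raster into a :class:`MultibandImage`.

    ``band_labels`` must match the band count when given; single-band files
    default to ``["TIR"]`` only if labelled so by the caller, otherwise
    ``["band0"...]`` placeholders are used.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise IOError(f"unsupported raster format: {suffix}")
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    elif arr.ndim == 3 and arr.shape[0] < min(arr.shape[1:]) and arr.shape[2] > 16:
        # planar (B, H, W) layout some writers emit
        arr = np.moveaxis(arr, 0, 2)
    if band_labels is None:
        band_labels = [f"band{i}" for i in range(arr.shape[2])]
    return MultibandImage(arr, list(band_labels), nodata_value=nodata_value)


def write_image(img: MultibandImage, path) -> None:
    """Write as TIFF (any dtype/band count) or PNG (uint8, <=4 bands)."""
    path = Path(path)
    px = img.pixels
    if path.suffix.lower() in (".tif", ".tiff"):
        data = px[:, :, 0] if px.shape[2] == 1 else px
        tifffile.imwrite(str(path), data)
    elif path.suffix.lower() == ".png":
        if px.dtype != np.uint8:
            raise IOError("PNG output requires uint8 pixels")
        Image.fromarray(px[:, :, 0] if px.shape[2] == 1 else px).save(path)
    else:
        raise IOError(f"unsupported raster format: {path.suffix}")


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean raster as a single-band 8-bit 0/1 file."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {mask.shape}")
    write_image(
        MultibandImage(mask.astype(np.uint8), ["mask"]), path
    )


def read_mask(path) -> np.ndarray:
    """Read a 0/1 raster back into a boolean array."""
    img = read_image(path)
    if img.n_bands != 1:
        raise ValidationError(f"mask file has {img.n_bands} bands, expected 1")
    return img.pixels[:, :, 0] != 0


def read_vine_table(path) -> list[VineRecord]:
    """Read a vine table CSV with columns vine_id, zone_label, swp_mpa."""
    df = pd.read_csv(path)
    missing = {"vine_id", "zone_label", "swp_mpa"} - set(df.columns)
    if missing:
        raise ValidationError(f"vine table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        swp = None if pd.isna(row.swp_mpa) else float(row.swp_mpa)
        records.append(VineRecord(str(row.vine_id), int(row.zone_label), swp))
    return records


def write_vine_table(vines: list[VineRecord], path) -> None:
    pd.DataFrame(
        [(v.vine_id, v.zone_label, v.swp_mpa) for v in vines],
        columns=["vine_id", "zone_label", "swp_mpa"],
    ).to_csv(path, index=False)
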