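"""Classification-agreement metrics and the CWSI-SWP regression diagnostics.

Shadow-mask accuracy is assessed against manually marked reference pixels
with a binary confusion matrix, the percentage of correctly classified
shadow (precision of the predicted-shadow class) and Cohen's kappa, the
chance-corrected agreement

    kappa = (p_o - p_e) / (1 - p_e),

with observed agreement p_o = trace/total and expected agreement
p_e = sum_i row_i * col_i / total^2.  For reporting, percentages are rounded
to integers and kappa is truncated to two decimals (the convention of the
reference tables this module reproduces); full precision is always returned
by the computing functions themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "ConfusionMatrix2x2",
    "RegressionResult",
    "confusion_matrix",
    "shadow_precision",
    "cohens_kappa",
    "regress_cwsi_swp",
    "format_percent",
    "format_kappa",
    "reference_confusion_matrices",
]


@dataclass
class ConfusionMatrix2x2:
    """Counts with rows = observed {shadow, no-shadow}, cols = predicted."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (2, 2):
            raise ValidationError(f"need a 2x2 table, got shape {c.shape}")
        if (c < 0).any():
            raise ValidationError("counts must be non-negative")
        if c.sum() == 0:
            raise ValidationError("empty confusion matrix")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class RegressionResult:
    """OLS fit of SWP (MPa) on CWSI with the three reported diagnostics.

    ``rmse`` is the root mean squared residual (n denominator); ``se`` is
    the residual standard error (n-2 denominator).  Both in MPa.
    """

    slope: float
    intercept: float
    r2: float
    rmse: float
    se: float
    n: int


def confusion_matrix(observed: np.ndarray, predicted: np.ndarray,
                     valid: np.ndarray | None = None) -> ConfusionMatrix2x2:
    """Pixel-count confusion matrix of two boolean rasters (True = shadow)."""
    observed = np.asarray(observed, bool)
    predicted = np.asarray(predicted, bool)
    if observed.shape != predicted.shape:
        raise ValidationError(
            f"shape mismatch: {observed.shape} vs {predicted.shape}"
        )
    if valid is not None:
        valid = np.asarray(valid, bool)
        observed, predicted = observed[valid], predicted[valid]
    counts = np.array([
        [(observed & predicted).sum(), (observed & ~predicted).sum()],
        [(~observed & predicted).sum(), (~observed & ~predicted).sum()],
    ])
    return ConfusionMatrix2x2(counts)


def shadow_precision(cm: ConfusionMatrix2x2) -> float | None:
    """Percentage of predicted-shadow pixels that are truly shadow.

    100 * TP / (TP + FP) over the predicted-shadow column.  Returns None
    when nothing was predicted as shadow (undefined, reported missing).
    """
    c = cm.counts
    denom = c[0, 0] + c[1, 0]
    if denom == 0:
        return None
    return 100.0 * c[0, 0] / denom


def cohens_kappa(cm: ConfusionMatrix2x2) -> float | None:
    """Chance-corrected agreement; None when marginals are degenerate."""
    c = cm.counts.astype(float)
    total = c.sum()
    p_o = np.trace(c) / total
    p_e = float(c.sum(axis=1) @ c.sum(axis=0)) / total ** 2
    if p_e == 1.0:
        return None
    return float((p_o - p_e) / (1.0 - p_e))


def format_percent(value: float | None) -> int | None:
    """Report rounding for the percent column: nearest integer."""
    if value is None:
        return None
    return int(np.round(value))


def format_kappa(value: float | None) -> float | None:
    """Report rounding for kappa: truncation to 2 decimals."""
    if value is None:
        return None
    return floor(value * 100) / 100 if value >= 0 else -floor(-value * 100) / 100


def regress_cwsi_swp(cwsi, swp) -> RegressionResult:
    """Ordinary least squares of per-vine SWP on per-vine mean CWSI."""
    cwsi = np.asarray(cwsi, float)
    swp = np.asarray(swp, float)
    if cwsi.shape != swp.shape or cwsi.ndim != 1:
        raise ValidationError("cwsi and swp must be equal-length 1-D arrays")
    ok = np.isfinite(cwsi) & np.isfinite(swp)
    cwsi, swp = cwsi[ok], swp[ok]
    n = len(cwsi)
    if n < 3:
        raise ValidationError(f"need >= 3 complete pairs, have {n}")
    if np.ptp(cwsi) == 0:
        raise ValidationError("constant CWSI predictor")
    fit = sps.linregress(cwsi, swp)
    resid = swp - (fit.slope * cwsi + fit.intercept)
    ssr = float((resid ** 2).sum())
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue ** 2),
        rmse=float(np.sqrt(ssr / n)),
        se=float(np.sqrt(ssr / (n - 2))),
        n=n,
    )


# Published benchmark: per-band confusion matrices of K-means++ shadow
# classification against manually marked vineyard reference pixels, for the
# six camera bands.  Rows observed {shadow, no-shadow}, cols predicted.
_REFERENCE_MATRICES = {
    "490": [[8220, 1600], [910, 11630]],
    "550": [[9090, 730], [4280, 8260]],
    "680": [[8290, 1530], [1030, 11510]],
    "720": [[9470, 350], [2900, 9640]],
    "800": [[9630, 190], [5060, 7480]],
    "900": [[9820, 0], [7000, 5540]],
}


def reference_confusion_matrices() -> dict[str, ConfusionMatrix2x2]:
    """The published per-band shadow confusion matrices (band label -> table)."""
    return {band: ConfusionMatrix2x2(np.array(c))
            for band, c in _REFERENCE_MATRICES.items()}
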