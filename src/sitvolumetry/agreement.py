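"""Method-agreement statistics for paired volume measurements.

Three classical tools quantify how well a test method (e.g. MRI volumetry)
reproduces a reference (mass-derived truth or CT):

* **Lin's concordance correlation coefficient** rho_c = 2 s_xy /
  (s_x^2 + s_y^2 + (xbar - ybar)^2), computed with population (1/n)
  moments — the original estimator.  It factors into precision x accuracy:
  rho_c = rho * C_b, where rho is the Pearson correlation and C_b in (0, 1]
  is the bias-correction factor penalising location and scale shifts.
* **Reduced major axis (RMA) regression**: the symmetric line fit
  slope = sign(rho) * s_y / s_x, intercept = ybar - slope * xbar,
  appropriate when both variables carry measurement error.
* **Percent-based Bland-Altman**: per-pair percent differences
  d_i = 100 (y_i - x_i) / x_i relative to the reference; bias = mean(d),
  limits of agreement = bias +/- 1.96 * SD(d) with the sample (n-1) SD.

The model-fitting surface follows the estimator/results idiom:
``MethodAgreement(x, y).fit()`` returns a results object with the three
analyses, a ``summary()`` table and plotting helpers, and
``ThresholdCalibration(cases, c_grid).fit()`` sweeps the SIT threshold C
over segmentation cases and selects the C with the highest rho_c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .segmentation import SphericalROI, segment_sit
from .volumetry import mask_volume
from .image import VolumetricImage

__all__ = [
    "ConcordanceResult",
    "RmaFit",
    "BlandAltmanResult",
    "lin_ccc",
    "rma_fit",
    "bland_altman_percent",
    "calibrate_threshold",
    "MethodAgreement",
    "MethodAgreementResults",
    "ThresholdCalibration",
    "ThresholdCalibrationResults",
    "DEFAULT_C_GRID",
]

DEFAULT_C_GRID = (0.20, 0.30, 0.40, 0.50)
LOA_MULTIPLIER = 1.96


def _validate_pairs(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be 1D vectors of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in paired data")
    return x, y


@dataclass(frozen=True)
class ConcordanceResult:
    """Pearson rho, bias-correction factor C_b, and Lin's rho_c."""

    rho: float
    c_b: float
    rho_c: float


@dataclass(frozen=True)
class RmaFit:
    slope: float
    intercept: float

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class BlandAltmanResult:
    """Percent-difference bias and limits of agreement."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float


def lin_ccc(x, y, ddof: int = 0) -> ConcordanceResult:
    """Lin's concordance correlation coefficient with decomposition.

    ``ddof=0`` (population moments) is the canonical 1989 estimator; pass
    ``ddof=1`` for the sample-moment variant.
    """
    x, y = _validate_pairs(x, y)
    sx2 = x.var(ddof=ddof)
    sy2 = y.var(ddof=ddof)
    if sx2 == 0 or sy2 == 0:
        raise ValueError("correlation undefined for a constant vector")
    n = len(x)
    sxy = ((x - x.mean()) * (y - y.mean())).sum() / (n - ddof)
    rho = sxy / np.sqrt(sx2 * sy2)
    rho_c = 2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)
    c_b = rho_c / rho
    return ConcordanceResult(float(rho), float(c_b), float(rho_c))


def rma_fit(x, y) -> RmaFit:
    """Reduced major axis regression: slope = sign(rho) * s_y / s_x."""
    x, y = _validate_pairs(x, y)
    sx = x.std(ddof=0)
    sy = y.std(ddof=0)
    if sx == 0 or sy == 0:
        raise ValueError("RMA fit undefined for a constant vector")
    rho = np.corrcoef(x, y)[0, 1]
    sign = 1.0 if rho >= 0 else -1.0
    slope = sign * sy / sx
    intercept = y.mean() - slope * x.mean()
    return RmaFit(float(slope), float(intercept))


def bland_altman_percent(x, y) -> BlandAltmanResult:
    """Percent Bland-Altman relative to the reference ``x``.

    d_i = 100 (y_i - x_i) / x_i; bias = mean, LoA = bias +/- 1.96 * SD
    (sample SD, n-1 denominator).
    """
    x, y = _validate_pairs(x, y)
    if np.any(x <= 0):
        raise ValueError("reference values must be strictly positive")
    d = 100.0 * (y - x) / x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias, sd, bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd
    )


# ----------------------------------------------------------- model objects


class MethodAgreement:
    """Agreement model for a test method against a reference.

    Parameters
    ----------
    x : reference volumes (mm^3), strictly positive for Bland-Altman
    y : test volumes (mm^3)
    """

    def __init__(self, x, y, xname: str = "reference", yname: str = "test"):
        self.x, self.y = _validate_pairs(x, y)
        self.xname = xname
        self.yname = yname

    def fit(self) -> "MethodAgreementResults":
        return MethodAgreementResults(
            model=self,
            concordance=lin_ccc(self.x, self.y),
            rma=rma_fit(self.x, self.y),
            bland_altman=bland_altman_percent(self.x, self.y),
        )


@dataclass
class MethodAgreementResults:
    model: MethodAgreement
    concordance: ConcordanceResult
    rma: RmaFit
    bland_altman: BlandAltmanResult

    @property
    def nobs(self) -> int:
        return len(self.model.x)

    def to_dict(self) -> dict:
        ba = self.bland_altman
        cc = self.concordance
        return {
            "n": self.nobs,
            "rho": cc.rho,
            "c_b": cc.c_b,
            "rho_c": cc.rho_c,
            "rma_slope": self.rma.slope,
            "rma_intercept": self.rma.intercept,
            "bias_pct": ba.bias,
            "sd_pct": ba.sd,
            "loa_low_pct": ba.loa_low,
            "loa_high_pct": ba.loa_high,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            f"Method agreement: {self.model.yname} vs {self.model.xname} "
            f"(n = {d['n']})",
            "-" * 58,
            f"Pearson rho            {d['rho']:10.4f}",
            f"Bias correction C_b    {d['c_b']:10.4f}",
            f"Lin's rho_c            {d['rho_c']:10.4f}",
            f"RMA slope              {d['rma_slope']:10.4f}",
            f"RMA intercept          {d['rma_intercept']:10.3f} mm^3",
            f"Bland-Altman bias      {d['bias_pct']:10.2f} %",
            f"Limits of agreement    [{d['loa_low_pct']:.2f}, "
            f"{d['loa_high_pct']:.2f}] %",
        ]
        return "\n".join(lines)

    def plot_concordance(self, ax=None):
        """Scatter of test vs reference with equality and RMA lines."""
        from .plotting import plot_concordance

        return plot_concordance(self, ax=ax)

    def plot_bland_altman(self, ax=None):
        from .plotting import plot_bland_altman

        return plot_bland_altman(self, ax=ax)


def calibrate_threshold(
    cases: Sequence[tuple[VolumetricImage, SphericalROI, float]],
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    keep_largest: bool = False,
    segmenter: Callable | None = None,
) -> tuple[pd.DataFrame, float, list[dict]]:
    """Sweep the SIT threshold C over segmentation cases.

    For each C in the grid every case is segmented, the mask volume is
    measured, and concordance against the true volumes is computed.  The
    selected C maximises rho_c, with ties broken toward the smaller
    (more inclusive) C.

    Returns ``(table, selected_c, errors)``; per-case segmentation failures
    are recorded in ``errors`` and the case is dropped from every C so the
    pairings stay consistent.
    """
    if len(cases) < 3:
        raise ValueError("calibration needs at least 3 cases")
    if segmenter is None:
        segmenter = segment_sit
    c_grid = sorted(float(c) for c in c_grid)

    volumes: dict[float, list[float]] = {c: [] for c in c_grid}
    truths: list[float] = []
    errors: list[dict] = []
    for i, (image, roi, v_true) in enumerate(cases):
        per_c = {}
        try:
            for c in c_grid:
                per_c[c] = mask_volume(segmenter(image, roi, c, keep_largest))
        except Exception as exc:  # recorded, not fatal
            errors.append({"case": i, "error": f"{type(exc).__name__}: {exc}"})
            continue
        truths.append(float(v_true))
        for c in c_grid:
            volumes[c].append(per_c[c])

    if len(truths) < 3:
        raise ValueError("fewer than 3 cases segmented successfully")

    rows = []
    for c in c_grid:
        cc = lin_ccc(truths, volumes[c])
        rows.append(
            {"c": c, "n": len(truths), "rho": cc.rho, "c_b": cc.c_b, "rho_c": cc.rho_c}
        )
    table = pd.DataFrame(rows)
    # argmax rho_c; exact ties broken toward the smaller C
    selected = float(table.loc[table["rho_c"] == table["rho_c"].max(), "c"].min())
    return table, selected, errors


class ThresholdCalibration:
    """Calibration model for the SIT threshold C.

    ``cases`` are ``(image, roi, true_volume)`` triples; ``fit()`` segments
    every case at every C in the grid and selects the C with the highest
    Lin's rho_c against the true volumes.
    """

    def __init__(
        self,
        cases: Sequence[tuple[VolumetricImage, SphericalROI, float]],
        c_grid: Sequence[float] = DEFAULT_C_GRID,
        keep_largest: bool = False,
    ):
        self.cases = list(cases)
        self.c_grid = tuple(sorted(float(c) for c in c_grid))
        self.keep_largest = keep_largest

    def fit(self) -> "ThresholdCalibrationResults":
        table, selected, errors = calibrate_threshold(
            self.cases, self.c_grid, self.keep_largest
        )
        return ThresholdCalibrationResults(
            model=self, table=table, selected_c=selected, errors=errors
        )


@dataclass
class ThresholdCalibrationResults:
    model: ThresholdCalibration
    table: pd.DataFrame  # columns: c, n, rho, c_b, rho_c
    selected_c: float
    errors: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"SIT threshold calibration over {len(self.model.cases)} cases",
            "-" * 48,
            self.table.to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            ),
            f"selected C = {self.selected_c:.2f} (argmax rho_c)",
        ]
        if self.errors:
            lines.append(f"segmentation failures: {len(self.errors)}")
        return "\n".join(lines)
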