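"""Image-quality and uptake metrics: NEMA NU4 spill-over ratio, SUVmax,
hot/cold contrast, percent difference, and the fraction-vs-activity line fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phantoms import VOISpec
from .reconstruction import ImageVolume

__all__ = ["FitResult", "MetricReport", "spillover_ratio", "suv_max",
           "suv_mean", "contrast", "linear_fit", "percent_difference"]


@dataclass(frozen=True)
class FitResult:
    """Ordinary least-squares line fit of fraction (%) vs activity (µCi)."""

    slope: float          # %/µCi
    intercept: float      # %
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("need at least 2 points")
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")

    def predict(self, activity_uci) -> np.ndarray:
        return self.slope * np.asarray(activity_uci, float) + self.intercept


@dataclass(frozen=True)
class MetricReport:
    metric: str
    value: float
    voi_labels: tuple[str, ...] = ()
    image_id: str = ""


def _voi_values(img: ImageVolume, voi: VOISpec) -> np.ndarray:
    xx, yy = img.coords_mm()
    mask = voi.mask(xx, yy, 0.0)
    vals = img.values[mask]
    if vals.size == 0:
        raise ValueError(f"VOI {voi.label or voi.center_mm} is empty "
                         "(outside the image?)")
    return vals


def spillover_ratio(img: ImageVolume, cold: VOISpec, uniform: VOISpec
                    ) -> float:
    """NEMA NU4 spill-over ratio in percent:
    100 × mean(cold VOI) / mean(uniform VOI)."""
    cold_mean = float(_voi_values(img, cold).mean())
    uniform_mean = float(_voi_values(img, uniform).mean())
    if uniform_mean <= 0:
        raise ValueError("uniform-region mean must be positive")
    return 100.0 * cold_mean / uniform_mean


def suv_max(img: ImageVolume, roi: VOISpec) -> float:
    """Maximum voxel value in the ROI (SUVmax; robust to partial-volume
    dilution of the mean)."""
    return float(_voi_values(img, roi).max())


def suv_mean(img: ImageVolume, roi: VOISpec) -> float:
    return float(_voi_values(img, roi).mean())


def contrast(img: ImageVolume, hot: VOISpec, cold: VOISpec,
             statistic: str = "max") -> float:
    """Hot-to-cold uptake contrast, SUV(hot)/SUV(cold), using the configured
    SUV statistic (default SUVmax)."""
    fn = {"max": suv_max, "mean": suv_mean}[statistic]
    hot_v = fn(img, hot)
    cold_v = fn(img, cold)
    if cold_v <= 0:
        raise ValueError("cold-region SUV must be positive")
    return hot_v / cold_v


def linear_fit(activities_uci, fractions_percent) -> FitResult:
    """OLS fit of fraction (%) against activity (µCi).

    R² = 1 − SSres/SStot; a constant-y input returns slope 0 and R² = 0."""
    x = np.asarray(activities_uci, float)
    y = np.asarray(fractions_percent, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least 2 paired points")
    if np.allclose(y, y[0]):
        return FitResult(0.0, float(y[0]), 0.0, int(x.size))
    res = stats.linregress(x, y)
    return FitResult(float(res.slope), float(res.intercept),
                     float(res.rvalue**2), int(x.size))


def percent_difference(value: float, reference: float) -> float:
    """100 × |value − reference| / reference (reference = gold standard)."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * abs(value - reference) / abs(reference)
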