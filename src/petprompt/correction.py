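"""Sinogram-domain correction of I-131 prompt-emission contamination.

Prompt gammas paired accidentally with each other produce a nearly uniform
background across the sinogram (their emission directions are uncorrelated
with the annihilation photons).  The correction therefore:

1. estimates the smooth background level from the sinogram *tails* — per
   projection angle the object support is found by thresholding the radial
   profile, and the level is fitted from the bins outside the support;
2. scales that background shape so its total equals the prompt-emission
   contamination fraction of the recorded prompts (the scale factor of the
   subtraction is the contamination fraction);
3. subtracts the prompt-gamma estimate (and, optionally, a residual scatter
   share) from the uncorrected sinogram, clamping negative bins to zero.

The fraction itself can come from the packaged calibration table, from the
published linear activity model, from the closed-form rate model, or be
supplied directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .acquisition import Sinogram
from .tables import FractionTable, load_fraction_table

__all__ = [
    "CorrectionResult", "fraction_from_table", "fraction_linear_model",
    "estimate_background_sinogram", "correct_sinogram",
]


def fraction_from_table(activity_uci: float, window,
                        table: FractionTable | None = None) -> float:
    """Contamination fraction (%) from the packaged calibration table.

    Exact at tabulated activities, piecewise-linear in between, 0 at zero
    activity.  Raises for non-tabulated windows or activities above the
    table range (10 mCi)."""
    table = table or load_fraction_table()
    return table.lookup(activity_uci, window)


#: Published linear model of fraction (%) vs I-131 activity (µCi) in the
#: 350–650 keV window: 0.06·A − 6.72 (R² = 0.99), fitted over 100–1000 µCi.
LINEAR_MODEL_SLOPE = 0.06
LINEAR_MODEL_INTERCEPT = -6.72
_LINEAR_MODEL_RANGE = (100.0, 1000.0)


def fraction_linear_model(activity_uci: float) -> float:
    """Linear-model contamination fraction max(0, 0.06·A − 6.72) percent.

    Warns outside the 100–1000 µCi range the model was fitted on."""
    a = float(activity_uci)
    if a < 0:
        raise ValueError("activity must be non-negative")
    if not _LINEAR_MODEL_RANGE[0] <= a <= _LINEAR_MODEL_RANGE[1]:
        warnings.warn(
            f"linear fraction model evaluated at {a} µCi, outside its "
            f"{_LINEAR_MODEL_RANGE} µCi validity range", stacklevel=2)
    return max(0.0, LINEAR_MODEL_SLOPE * a + LINEAR_MODEL_INTERCEPT)


def estimate_background_sinogram(uncorrected: Sinogram,
                                 method: str = "tail-uniform",
                                 support_threshold: float = 0.10,
                                 smooth_sigma_angles: float = 8.0) -> Sinogram:
    """Estimate the smooth out-of-body background of a sinogram.

    Per angle, the object support is the radial span between the first and
    last bin exceeding the per-angle baseline (profile minimum) by
    ``support_threshold`` × the profile's range above that baseline; the
    background level is fitted from the bins outside all supports:

    * ``"tail-uniform"`` — one global mean tail level (flat background);
    * ``"tail-gaussian"`` — per-angle tail means, Gaussian-smoothed along the
      angle axis (allows slow angular variation).

    An all-zero sinogram returns a zero background.  If every angle's support
    covers the full radial range there are no tails and the background cannot
    be estimated (raises).
    """
    counts = uncorrected.counts
    if counts.size == 0:
        raise ValueError("empty sinogram")
    if counts.sum() == 0:
        return Sinogram(np.zeros_like(counts),
                        {**uncorrected.meta, "kind": "background-estimate"})
    if method not in ("tail-uniform", "tail-gaussian"):
        raise ValueError(f"unknown method {method!r}")

    n_ang, n_rad = counts.shape
    tail_mask = np.zeros_like(counts, dtype=bool)
    for k in range(n_ang):
        prof = counts[k]
        # threshold above the per-angle baseline so a strong flat background
        # does not swallow the tails
        base = prof.min()
        cut = base + support_threshold * (prof.max() - base)
        above = np.flatnonzero(prof > cut)
        if above.size == 0:
            tail_mask[k] = True
            continue
        lo, hi = above[0], above[-1]
        tail_mask[k, :lo] = True
        tail_mask[k, hi + 1:] = True
    if not tail_mask.any():
        raise ValueError(
            "object support covers all radial bins; cannot estimate background")

    if method == "tail-uniform":
        level = counts[tail_mask].mean()
        bg = np.full_like(counts, level)
    else:
        per_angle = np.array([
            counts[k, tail_mask[k]].mean() if tail_mask[k].any() else np.nan
            for k in range(n_ang)])
        if np.isnan(per_angle).any():
            fill = np.nanmean(per_angle)
            per_angle = np.where(np.isnan(per_angle), fill, per_angle)
        per_angle = gaussian_filter1d(per_angle, smooth_sigma_angles,
                                      mode="wrap")
        bg = np.repeat(per_angle[:, None], n_rad, axis=1)
    return Sinogram(bg, {**uncorrected.meta, "kind": "background-estimate",
                         "method": method,
                         "support_threshold": support_threshold})


@dataclass
class CorrectionResult:
    """Outcome of the prompt-emission subtraction.

    Bin-wise, ``corrected + prompt_gamma + scatter = uncorrected`` up to the
    clamping of negative bins (``clamped_bins``/``clamped_mass``)."""

    corrected: Sinogram
    background: Sinogram
    prompt_gamma: Sinogram
    scatter: Sinogram
    fraction_percent: float
    clamped_bins: int
    clamped_mass: float


def correct_sinogram(uncorrected: Sinogram, fraction_percent: float,
                     method: str = "tail-uniform",
                     support_threshold: float = 0.10,
                     scatter_share: float = 0.0,
                     eq1_literal: bool = False) -> CorrectionResult:
    """Subtract the fraction-scaled prompt-gamma background from a sinogram.

    The background *shape* is estimated from the sinogram tails, then the
    prompt-gamma estimate is that shape normalized so its total equals
    ``f × sum(uncorrected)`` with ``f = fraction/100`` — i.e. the subtracted
    mass equals the contamination share of the recorded prompts.  With
    ``eq1_literal=True`` the estimate is instead the raw background estimate
    multiplied by ``f`` (the literal scale-factor reading, with no total
    normalization).  ``scatter_share`` (of the background estimate) is
    additionally subtracted as residual scatter; the default 0 leaves scatter
    handling to the upstream chain.

    Negative bins after subtraction are clamped to zero and counted; the
    remaining bins are not rescaled.  ``fraction = 0`` with no scatter share
    is the identity.
    """
    if not 0.0 <= fraction_percent < 100.0:
        raise ValueError("fraction must be in [0, 100) percent")
    if not 0.0 <= scatter_share <= 1.0:
        raise ValueError("scatter_share must be in [0, 1]")
    f = fraction_percent / 100.0
    if f == 0.0 and scatter_share == 0.0:  # identity; nothing to estimate
        zero = Sinogram(np.zeros_like(uncorrected.counts),
                        {**uncorrected.meta, "kind": "background-estimate"})
        return CorrectionResult(
            corrected=uncorrected.copy(corrected=True, fraction_percent=0.0),
            background=zero, prompt_gamma=zero.copy(kind="prompt-estimate"),
            scatter=zero.copy(kind="scatter-share"), fraction_percent=0.0,
            clamped_bins=0, clamped_mass=0.0)
    bg = estimate_background_sinogram(uncorrected, method=method,
                                      support_threshold=support_threshold)
    if eq1_literal:
        prompt = bg.counts * f
    else:
        total = uncorrected.total
        bg_total = bg.counts.sum()
        if bg_total > 0:
            prompt = bg.counts * (f * total / bg_total)
        else:  # degenerate: no tail signal; fall back to a flat shape
            prompt = np.full_like(uncorrected.counts,
                                  f * total / uncorrected.counts.size)
    scatter = bg.counts * scatter_share
    residual = uncorrected.counts - prompt - scatter
    clamped = residual < 0
    corrected = np.where(clamped, 0.0, residual)
    meta = {**uncorrected.meta, "corrected": True,
            "fraction_percent": fraction_percent, "method": method,
            "scatter_share": scatter_share, "eq1_literal": eq1_literal}
    return CorrectionResult(
        corrected=Sinogram(corrected, meta),
        background=bg,
        prompt_gamma=Sinogram(prompt, {**bg.meta, "kind": "prompt-estimate"}),
        scatter=Sinogram(scatter, {**bg.meta, "kind": "scatter-share"}),
        fraction_percent=fraction_percent,
        clamped_bins=int(clamped.sum()),
        clamped_mass=float(-residual[clamped].sum()),
    )
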