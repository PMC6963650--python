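"""Packaged calibration data.

Two small tables ship with the package:

* the I-131 prompt-emission fraction surface — contamination fraction (%) of
  recorded coincidences as a function of I-131 activity (1 µCi – 10 mCi, with
  100 µCi of F-18) for the four acquisition energy windows in which it is
  non-trivial — validated against an embedded checksum at load time;
* a coarse detector response lookup (interaction probability and photopeak
  fraction vs. photon energy) for an LSO-like small-animal PET block, used by
  the semi-analytic detection model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["FractionTable", "load_fraction_table", "load_detector_response",
           "DetectorResponse", "TABLE_WINDOWS"]

_FRACTION_SHA256 = (
    "47419d317d46446bea9d8676a821ad8eb2f125670618748b9e4ced3c58888972"
)
_RESPONSE_SHA256 = (
    "7960371068acd86bc7d3f3904b4e88e271ea35e8414b3395fbc02f03bcfbe1c7"
)

#: The four energy windows (keV, half-open) the fraction surface tabulates.
TABLE_WINDOWS = ((350, 650), (350, 750), (450, 650), (450, 750))


def _read_packaged(name: str, sha256: str) -> bytes:
    raw = resources.files("petprompt.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != sha256:
        raise ValueError(
            f"packaged table {name} is corrupted (checksum mismatch: {digest})"
        )
    return raw


@dataclass(frozen=True)
class FractionTable:
    """Prompt-emission contamination fraction (%) by activity × window."""

    activities_uci: np.ndarray          # shape (n,), ascending
    windows: tuple[tuple[int, int], ...]
    fractions: pd.DataFrame             # index activity, columns "low-high"

    def _column(self, window) -> str:
        lo, hi = int(window[0]), int(window[1])
        key = f"{lo}-{hi}"
        if key not in self.fractions.columns:
            raise KeyError(
                f"window [{lo},{hi}) keV is not tabulated; "
                f"available: {list(self.fractions.columns)}"
            )
        return key

    def lookup(self, activity_uci: float, window) -> float:
        """Exact value at tabulated activities; piecewise-linear in between;
        0 at activity 0.  Raises above the tabulated range."""
        col = self._column(window)
        a = float(activity_uci)
        if a < 0:
            raise ValueError("activity must be non-negative")
        amax = float(self.activities_uci[-1])
        if a > amax:
            raise ValueError(
                f"activity {a} µCi is above the tabulated range (max {amax})"
            )
        xs = np.concatenate([[0.0], self.activities_uci])
        ys = np.concatenate([[0.0], self.fractions[col].to_numpy(float)])
        return float(np.interp(a, xs, ys))

    def column(self, window, activities=None) -> tuple[np.ndarray, np.ndarray]:
        """(activities, fractions) arrays for one window, optionally restricted
        to a subset of tabulated activities."""
        col = self._column(window)
        acts = self.activities_uci
        vals = self.fractions[col].to_numpy(float)
        if activities is not None:
            mask = np.isin(acts, np.asarray(activities, float))
            acts, vals = acts[mask], vals[mask]
        return acts, vals

    def to_csv(self) -> str:
        df = self.fractions.copy()
        df.insert(0, "activity_uci", self.activities_uci)
        return df.to_csv(index=False, float_format="%.2f")

    @classmethod
    def from_csv_text(cls, text: str) -> "FractionTable":
        df = pd.read_csv(pd.io.common.StringIO(text))
        acts = df.pop("activity_uci").to_numpy(float)
        windows = tuple(tuple(int(x) for x in c.split("-")) for c in df.columns)
        df.index = pd.Index(acts, name="activity_uci")
        for col in df.columns:
            v = df[col].to_numpy(float)
            if np.any(v < 0) or np.any(v > 100):
                raise ValueError(f"fractions out of [0, 100] in column {col}")
            if np.any(np.diff(v) < 0):
                raise ValueError(f"column {col} is not non-decreasing in activity")
        return cls(acts, windows, df)


def load_fraction_table() -> FractionTable:
    """Load and validate the packaged contamination-fraction table."""
    raw = _read_packaged("i131_prompt_fraction.csv", _FRACTION_SHA256)
    return FractionTable.from_csv_text(raw.decode())


@dataclass(frozen=True)
class DetectorResponse:
    """Energy-interpolated intrinsic detector response (LSO-like block)."""

    energy_kev: np.ndarray
    interaction_prob: np.ndarray
    photopeak_fraction: np.ndarray

    def interaction(self, e_kev) -> np.ndarray:
        return np.interp(e_kev, self.energy_kev, self.interaction_prob)

    def photopeak(self, e_kev) -> np.ndarray:
        return np.interp(e_kev, self.energy_kev, self.photopeak_fraction)


def load_detector_response() -> DetectorResponse:
    raw = _read_packaged("detector_response.csv", _RESPONSE_SHA256)
    df = pd.read_csv(pd.io.common.StringIO(raw.decode()))
    return DetectorResponse(
        df["energy_kev"].to_numpy(float),
        df["interaction_prob"].to_numpy(float),
        df["photopeak_fraction"].to_numpy(float),
    )
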