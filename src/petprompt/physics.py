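"""Radionuclide emission models and activity units for F-18 and I-131.

The two nuclides relevant to FDG-PET follow-up during radioiodine therapy are
modelled at the level PET contamination analysis needs: discrete emission
lines with branching intensities.  F-18 is a (nearly) pure positron emitter
whose signal is the back-to-back 511 keV annihilation pair; I-131 emits no
positrons but a set of prompt single gammas (284, 364, 637, 723 keV) plus
therapeutic betas.  The prompt gammas are the contamination mechanism: they
fall inside typical small-animal PET energy windows and, paired accidentally,
produce a near-uniform background in the sinogram.

Beta lines are carried for bookkeeping only; they are assumed to deposit no
detector signal (they do not escape the subject).
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmissionLine",
    "RadionuclideSpec",
    "Activity",
    "UCI_TO_BQ",
    "builtin_radionuclides",
    "activity_to_decay_rate",
    "sample_decay_photons",
    "specs_to_csv",
    "specs_from_csv",
]

#: Exact definition: 1 µCi = 3.7e4 decays per second.
UCI_TO_BQ = 3.7e4

_KINDS = ("prompt-gamma", "annihilation-pair", "beta")


@dataclass(frozen=True)
class EmissionLine:
    """A single decay emission branch.

    Parameters
    ----------
    energy_kev : float
        Photon (or beta endpoint) energy in keV; must be positive.
    intensity : float
        Emission probability per decay, in [0, 1].
    kind : str
        One of ``"prompt-gamma"``, ``"annihilation-pair"``, ``"beta"``.
    """

    energy_kev: float
    intensity: float
    kind: str

    def __post_init__(self) -> None:
        if self.energy_kev <= 0:
            raise ValueError(f"energy must be positive, got {self.energy_kev}")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"intensity must be in [0, 1], got {self.intensity}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "annihilation-pair" and self.energy_kev != 511.0:
            raise ValueError("annihilation-pair lines are always 511 keV")


@dataclass(frozen=True)
class RadionuclideSpec:
    """Decay emission model of one radionuclide."""

    name: str
    half_life_s: float
    lines: tuple[EmissionLine, ...]
    positron_yield: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positron_yield <= 1.0:
            raise ValueError("positron_yield must be in [0, 1]")
        if self.half_life_s <= 0:
            raise ValueError("half_life_s must be positive")
        object.__setattr__(self, "lines", tuple(self.lines))

    @property
    def gamma_lines(self) -> tuple[EmissionLine, ...]:
        """Prompt single-gamma lines (the contamination-relevant branches)."""
        return tuple(l for l in self.lines if l.kind == "prompt-gamma")

    def line(self, energy_kev: float) -> EmissionLine:
        for l in self.lines:
            if l.energy_kev == energy_kev:
                return l
        raise KeyError(f"{self.name} has no line at {energy_kev} keV")


@dataclass(frozen=True)
class Activity:
    """A radioactivity amount; canonical unit is µCi (matching the study's
    activity grid, 100–1000 µCi etc.).  Bq available via exact conversion."""

    uci: float

    def __post_init__(self) -> None:
        if self.uci < 0:
            raise ValueError(f"activity must be non-negative, got {self.uci}")

    @property
    def bq(self) -> float:
        return self.uci * UCI_TO_BQ

    @classmethod
    def from_bq(cls, bq: float) -> "Activity":
        return cls(bq / UCI_TO_BQ)

    def __float__(self) -> float:
        return float(self.uci)


def _as_activity(a) -> Activity:
    return a if isinstance(a, Activity) else Activity(float(a))


def activity_to_decay_rate(a) -> float:
    """Decay rate in decays/s for an activity given in µCi (or ``Activity``)."""
    return _as_activity(a).bq


# Printed branching values for I-131 (gammas 284/364/637/723 keV at
# 6/82/7/2 %, betas 334/606 keV at 7/90 %).  The gamma intensities are the
# rounded values in common use; a literature-refined variant (e.g. 81.5 % for
# the 364 keV line) can be selected with variant="literature".
_I131_LINES_DEFAULT = (
    EmissionLine(284.0, 0.06, "prompt-gamma"),
    EmissionLine(364.0, 0.82, "prompt-gamma"),
    EmissionLine(637.0, 0.07, "prompt-gamma"),
    EmissionLine(723.0, 0.02, "prompt-gamma"),
    EmissionLine(334.0, 0.07, "beta"),
    EmissionLine(606.0, 0.90, "beta"),
)

_I131_LINES_LITERATURE = (
    EmissionLine(284.3, 0.0612, "prompt-gamma"),
    EmissionLine(364.5, 0.815, "prompt-gamma"),
    EmissionLine(637.0, 0.0716, "prompt-gamma"),
    EmissionLine(722.9, 0.0177, "prompt-gamma"),
    EmissionLine(333.8, 0.0721, "beta"),
    EmissionLine(606.3, 0.894, "beta"),
)

_F18_LINES = (EmissionLine(511.0, 0.967, "annihilation-pair"),)

_HALF_LIFE_F18_S = 109.77 * 60.0
_HALF_LIFE_I131_S = 8.0252 * 86400.0


def builtin_radionuclides(variant: str = "default") -> dict[str, RadionuclideSpec]:
    """Packaged nuclide specs for ``"F-18"`` and ``"I-131"``.

    ``variant="literature"`` loads decay-table-refined intensities instead of
    the rounded default branching values.
    """
    if variant == "default":
        i131_lines = _I131_LINES_DEFAULT
    elif variant == "literature":
        i131_lines = _I131_LINES_LITERATURE
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return {
        "F-18": RadionuclideSpec(
            name="F-18",
            half_life_s=_HALF_LIFE_F18_S,
            lines=_F18_LINES,
            positron_yield=0.967,
        ),
        "I-131": RadionuclideSpec(
            name="I-131",
            half_life_s=_HALF_LIFE_I131_S,
            lines=i131_lines,
            positron_yield=0.0,
        ),
    }


def get_radionuclide(name: str) -> RadionuclideSpec:
    specs = builtin_radionuclides()
    try:
        return specs[name]
    except KeyError:
        raise KeyError(
            f"unknown nuclide {name!r}; built-ins: {sorted(specs)}"
        ) from None


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3) unit vectors uniform on the sphere."""
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def sample_decay_photons(spec: RadionuclideSpec, n_decays: int, seed) -> np.ndarray:
    """Sample the photons emitted by ``n_decays`` decays of ``spec``.

    Each prompt-gamma line fires independently with its branching intensity;
    an annihilation pair fires with probability ``positron_yield`` and yields
    two back-to-back photons.  Betas emit no photons.  Directions are
    isotropic.  Reproducible for a fixed seed.

    Returns
    -------
    numpy structured array with fields ``energy_kev`` (f8), ``direction``
    (f8, shape (3,)) and ``decay`` (i8, the decay index in [0, n_decays)).
    """
    if n_decays < 0:
        raise ValueError("n_decays must be >= 0")
    rng = np.random.default_rng(seed)
    dtype = np.dtype(
        [("energy_kev", "f8"), ("direction", "f8", (3,)), ("decay", "i8")]
    )
    chunks: list[np.ndarray] = []
    for line in spec.lines:
        if line.kind == "beta":
            continue
        fired = rng.random(n_decays) < line.intensity
        idx = np.flatnonzero(fired)
        if line.kind == "annihilation-pair":
            u = _isotropic_directions(idx.size, rng)
            rec = np.empty(2 * idx.size, dtype=dtype)
            rec["energy_kev"] = 511.0
            rec["direction"][0::2] = u
            rec["direction"][1::2] = -u
            rec["decay"][0::2] = idx
            rec["decay"][1::2] = idx
        else:
            rec = np.empty(idx.size, dtype=dtype)
            rec["energy_kev"] = line.energy_kev
            rec["direction"] = _isotropic_directions(idx.size, rng)
            rec["decay"] = idx
        chunks.append(rec)
    if not chunks:
        return np.empty(0, dtype=dtype)
    out = np.concatenate(chunks)
    return out[np.argsort(out["decay"], kind="stable")]


# -- CSV interchange ---------------------------------------------------------

def specs_to_csv(specs: dict[str, RadionuclideSpec]) -> str:
    """Serialize nuclide specs as CSV (nuclide, energy_keV, intensity, kind)."""
    buf = _io.StringIO()
    w = csv.writer(buf)
    w.writerow(["nuclide", "energy_keV", "intensity", "kind"])
    for name in sorted(specs):
        for line in specs[name].lines:
            w.writerow([name, repr(line.energy_kev), repr(line.intensity), line.kind])
    return buf.getvalue()


def specs_from_csv(text: str, half_lives: dict[str, float] | None = None,
                   positron_yields: dict[str, float] | None = None
                   ) -> dict[str, RadionuclideSpec]:
    """Inverse of :func:`specs_to_csv`.

    Half-lives and positron yields are not part of the line table; they are
    taken from the optional mappings, falling back to the built-ins.
    """
    builtins = builtin_radionuclides()
    lines: dict[str, list[EmissionLine]] = {}
    for row in csv.DictReader(_io.StringIO(text)):
        lines.setdefault(row["nuclide"], []).append(
            EmissionLine(float(row["energy_keV"]), float(row["intensity"]),
                         row["kind"])
        )
    out = {}
    for name, ls in lines.items():
        hl = (half_lives or {}).get(name)
        py = (positron_yields or {}).get(name)
        if name in builtins:
            hl = hl if hl is not None else builtins[name].half_life_s
            py = py if py is not None else builtins[name].positron_yield
        if hl is None:
            raise ValueError(f"half-life for {name!r} not provided")
        out[name] = RadionuclideSpec(name, hl, tuple(ls), py or 0.0)
    return out
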