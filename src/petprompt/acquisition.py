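"""Detection, energy windowing, coincidence formation and sinogram binning.

Two complementary paths estimate what a small-animal PET scanner records when
F-18 (annihilation pairs) and I-131 (prompt single gammas) are present
simultaneously:

* an **analytic rate-equation path** (:func:`counting_rates`): F-18 prompt
  coincidences are ``S_w × decay rate`` with the window sensitivity ``S_w``;
  I-131 contributes *accidental* coincidences formed by pairing two of its
  in-window singles within the coincidence timing window, at the closed-form
  rate ``τ·R_w²`` for a singles rate ``R_w`` (pairs accepted when
  ``|Δt| ≤ τ``; cross-stream accidentals follow the standard ``2τ·R₁·R₂``);
* an **event-level Monte Carlo path** (:func:`simulate_coincidences`):
  sampled decays, simplified transport (attenuation + at most one Compton
  scatter in the subject), energy-blurred detection, time pairing and
  event-by-event classification.

The single free scale of the semi-analytic detection model (``κ``, the I-131
singles-yield scale) is calibrated once against the packaged contamination
table at the 300 µCi, [350, 650) keV point; everything else is a prediction.

The contamination share of recorded coincidences — the *prompt-emission
fraction* — is ``100 × I-coincidences / (F-prompts + I-coincidences)``.  In
the closed form the two isotopes' rates are evaluated independently (as in
the single-isotope rate studies the calibration table derives from), so
cross-isotope accidentals are reported separately and do not enter the
fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .physics import (RadionuclideSpec, activity_to_decay_rate,
                      builtin_radionuclides)
from .tables import (DetectorResponse, FractionTable, load_detector_response,
                     load_fraction_table)

__all__ = [
    "EnergyWindow", "ScannerModel", "RateReport", "Coincidence", "Sinogram",
    "blur_energy", "singles_yield", "f18_sensitivity", "counting_rates",
    "simulate_coincidences", "prompt_emission_fraction", "bin_sinogram",
    "sample_contaminated_sinogram", "calibrate_scanner",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class EnergyWindow:
    """Accepted deposited-energy range in keV, half-open ``[low, high)``."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"require 0 < low < high, got [{self.low}, {self.high})")

    def contains(self, e_kev) -> np.ndarray:
        e = np.asarray(e_kev)
        return (e >= self.low) & (e < self.high)

    @property
    def key(self) -> str:
        return f"{self.low:g}-{self.high:g}"

    @classmethod
    def parse(cls, text: str) -> "EnergyWindow":
        lo, hi = text.split("-")
        return cls(float(lo), float(hi))


def _as_window(w) -> EnergyWindow:
    if isinstance(w, EnergyWindow):
        return w
    if isinstance(w, str):
        return EnergyWindow.parse(w)
    return EnergyWindow(float(w[0]), float(w[1]))


# F-18 coincidence sensitivities per acquisition window (fraction of decays),
# from the scanner-model Monte Carlo characterization of the Inveon:
# 7.0 % for 350-650, 7.3 % for 350-750, 5.8 % for 450-650, 6.0 % for 450-750.
_F18_SENSITIVITY = {
    "350-650": 0.070,
    "350-750": 0.073,
    "450-650": 0.058,
    "450-750": 0.060,
}


@dataclass(frozen=True)
class ScannerModel:
    """Inveon-like small-animal PET scanner constants.

    ``coincidence_window_ns`` (τ) defaults to the documented Inveon setting
    3.432 ns; pairs are accepted when ``|t₁ − t₂| ≤ τ``.
    ``singles_yield_scale`` (κ) is the single free calibration constant of the
    I-131 singles-yield model (see :func:`calibrate_scanner`).
    """

    ring_diameter_mm: float = 161.0
    axial_fov_mm: float = 127.0
    energy_resolution_fwhm_511: float = 0.11
    coincidence_window_ns: float = 3.432
    f18_coincidence_sensitivity: Mapping[str, float] = field(
        default_factory=lambda: dict(_F18_SENSITIVITY))
    singles_yield_scale: float = 1.0
    n_radial_bins: int = 128
    n_angles: int = 160
    radial_bin_mm: float = 0.8
    event_cap: int = 5_000_000

    def __post_init__(self) -> None:
        for name in ("ring_diameter_mm", "axial_fov_mm",
                     "energy_resolution_fwhm_511", "coincidence_window_ns",
                     "singles_yield_scale", "n_radial_bins", "n_angles",
                     "radial_bin_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ring_radius_mm(self) -> float:
        return self.ring_diameter_mm / 2.0

    @property
    def tau_s(self) -> float:
        return self.coincidence_window_ns * 1e-9

    @property
    def geometric_acceptance(self) -> float:
        """Solid-angle fraction of the detector band for a centred source."""
        zh = self.axial_fov_mm / 2.0
        return zh / math.hypot(zh, self.ring_radius_mm)

    @property
    def fov_mm(self) -> float:
        return self.n_radial_bins * self.radial_bin_mm

    def energy_fwhm(self, e_kev) -> np.ndarray:
        """Energy resolution FWHM(E) = r₅₁₁·√(511·E) keV — 1/√E fractional
        scaling anchored at the 511 keV resolution."""
        return self.energy_resolution_fwhm_511 * np.sqrt(511.0 * np.asarray(e_kev))

    def energy_sigma(self, e_kev) -> np.ndarray:
        return self.energy_fwhm(e_kev) / _FWHM_TO_SIGMA


_RESPONSE: DetectorResponse | None = None


def _response() -> DetectorResponse:
    global _RESPONSE
    if _RESPONSE is None:
        _RESPONSE = load_detector_response()
    return _RESPONSE


def blur_energy(e_kev, scanner: ScannerModel, seed=None, *,
                zero_variance: bool = False) -> np.ndarray:
    """Gaussian energy blur with FWHM(E) = r₅₁₁·√(511·E); mean preserved.

    ``zero_variance=True`` is a debug mode returning the input unchanged.
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    e = np.asarray(e_kev, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energies must be positive")
    if zero_variance:
        return e.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(e, scanner.energy_sigma(e))


def compton_edge_kev(e_kev) -> np.ndarray:
    """Maximum Compton-electron energy deposit for photon energy E:
    2E²/(511 + 2E)."""
    e = np.asarray(e_kev, dtype=float)
    return 2.0 * e * e / (511.0 + 2.0 * e)


def _photopeak_window_mass(e: float, window: EnergyWindow,
                           scanner: ScannerModel) -> float:
    """Mass of the blurred photopeak falling inside the window."""
    sig = float(scanner.energy_sigma(e))
    return float(stats.norm.cdf(window.high, e, sig)
                 - stats.norm.cdf(window.low, e, sig))


def _continuum_window_fraction(e: float, window: EnergyWindow,
                               scanner: ScannerModel) -> float:
    """In-window probability for a (flat-approximated) Compton-continuum
    deposit uniform on [0, edge], including the Gaussian energy blur."""
    edge = float(compton_edge_kev(e))
    if edge <= 0:
        return 0.0
    dep = np.linspace(edge / 128.0, edge, 64)
    sig = np.asarray(scanner.energy_sigma(dep))
    mass = (stats.norm.cdf(window.high, dep, sig)
            - stats.norm.cdf(window.low, dep, sig))
    return float(mass.mean())


def in_window_deposit_fraction(e_kev: float, window, scanner: ScannerModel) -> float:
    """Probability that a photon of energy E which interacts in the detector
    deposits an in-window energy (blurred photopeak + blurred flat Compton
    continuum approximation)."""
    window = _as_window(window)
    pf = float(_response().photopeak(e_kev))
    return (pf * _photopeak_window_mass(e_kev, window, scanner)
            + (1.0 - pf) * _continuum_window_fraction(e_kev, window, scanner))


def _photon_detection_prob(e_kev: float, window: EnergyWindow,
                           scanner: ScannerModel) -> float:
    """Intrinsic interaction probability × in-window deposit fraction (no
    geometry, no calibration scale)."""
    return float(_response().interaction(e_kev)) * in_window_deposit_fraction(
        e_kev, window, scanner)


def f18_sensitivity(window, scanner: ScannerModel) -> float:
    """F-18 coincidence sensitivity S_w (prompt pairs per decay).

    The four characterized windows use the configured values; any other
    window is predicted by scaling the semi-analytic pair-detection value,
    anchored at [350, 650)."""
    window = _as_window(window)
    sens = scanner.f18_coincidence_sensitivity
    if window.key in sens:
        return float(sens[window.key])
    anchor = EnergyWindow(350, 650)
    p = _photon_detection_prob(511.0, window, scanner)
    p0 = _photon_detection_prob(511.0, anchor, scanner)
    return float(sens[anchor.key]) * (p / p0) ** 2


def singles_yield(spec: RadionuclideSpec, window, scanner: ScannerModel) -> float:
    """In-window detected singles per decay (κ_w).

    Prompt-gamma emitters sum intensity × geometric acceptance × intrinsic
    interaction probability × in-window deposit fraction over their lines,
    scaled by the calibration constant κ.  For annihilation emitters the
    per-photon probability is tied to the configured pair sensitivity S_w
    through the pair-detection relation S_w = y·G·p² (positron yield y,
    geometric acceptance G), so the returned singles yield is 2·y·G·p.
    """
    window = _as_window(window)
    geo = scanner.geometric_acceptance
    if spec.positron_yield > 0:
        s_w = f18_sensitivity(window, scanner)
        p = math.sqrt(s_w / (spec.positron_yield * geo))
        return 2.0 * spec.positron_yield * geo * p
    total = 0.0
    for line in spec.gamma_lines:
        total += line.intensity * geo * _photon_detection_prob(
            line.energy_kev, window, scanner)
    return scanner.singles_yield_scale * total


def calibrate_scanner(scanner: ScannerModel | None = None,
                      table: FractionTable | None = None,
                      *, activity_uci: float = 300.0,
                      window=(350, 650),
                      f18_uci: float = 100.0) -> ScannerModel:
    """Fix the I-131 singles-yield scale κ from one table point.

    Solves ``τ·(κ·κ₀·λ_I)² / (S_w·λ_F) = odds(f_table)`` for κ, where κ₀ is
    the uncalibrated semi-analytic singles yield.  All other activities and
    windows then follow as predictions.
    """
    scanner = scanner or ScannerModel()
    table = table or load_fraction_table()
    window = _as_window(window)
    f = table.lookup(activity_uci, (window.low, window.high)) / 100.0
    odds = f / (1.0 - f)
    lam_i = activity_to_decay_rate(activity_uci)
    lam_f = activity_to_decay_rate(f18_uci)
    f_prompts = f18_sensitivity(window, scanner) * lam_f
    base = replace(scanner, singles_yield_scale=1.0)
    kappa0 = singles_yield(builtin_radionuclides()["I-131"], window, base)
    r_needed = math.sqrt(odds * f_prompts / base.tau_s)
    return replace(scanner, singles_yield_scale=r_needed / (kappa0 * lam_i))


# -- rate reports ------------------------------------------------------------

@dataclass(frozen=True)
class RateReport:
    """Analytic counting rates for one acquisition window (all cps)."""

    window: EnergyWindow
    f18_singles_cps: float
    i131_singles_cps: float
    f18_trues_cps: float
    f18_scatter_cps: float
    f18_randoms_cps: float
    i131_accidental_cps: float
    cross_randoms_cps: float

    @property
    def f18_prompts_cps(self) -> float:
        return self.f18_trues_cps + self.f18_scatter_cps

    @property
    def total_prompts_cps(self) -> float:
        return (self.f18_prompts_cps + self.f18_randoms_cps
                + self.i131_accidental_cps)

    @property
    def fraction_percent(self) -> float:
        """Prompt-emission contamination fraction,
        100 × I / (F-prompts + I)."""
        return prompt_emission_fraction(self)


def _phantom_activities(phantom) -> dict[str, float]:
    """Total activity (µCi) per isotope from a PhantomSpec or a plain
    ``{isotope: µCi}`` mapping."""
    if hasattr(phantom, "total_activity_uci"):
        return {name: phantom.total_activity_uci(name)
                for name in phantom.isotopes()}
    if isinstance(phantom, Mapping):
        return {k: float(v) for k, v in phantom.items()}
    raise TypeError(f"cannot interpret phantom of type {type(phantom)!r}")


def counting_rates(phantom, window, scanner: ScannerModel) -> RateReport:
    """Closed-form counting rates (analytic fast path).

    F-18 prompts = S_w·λ_F; I-131 contamination = accidental pairings among
    its in-window singles at rate τ·R_w²; cross-isotope accidentals
    2τ·R_I·R_F are reported but kept out of the contamination fraction (the
    two isotopes' prompts are evaluated independently, as in the
    single-isotope rate studies behind the calibration table).
    """
    window = _as_window(window)
    acts = _phantom_activities(phantom)
    if not acts or all(v <= 0 for v in acts.values()):
        raise ValueError("phantom holds no activity")
    specs = builtin_radionuclides()
    tau = scanner.tau_s

    lam_f = activity_to_decay_rate(acts.get("F-18", 0.0))
    lam_i = activity_to_decay_rate(acts.get("I-131", 0.0))
    r_f = singles_yield(specs["F-18"], window, scanner) * lam_f
    r_i = singles_yield(specs["I-131"], window, scanner) * lam_i
    trues = f18_sensitivity(window, scanner) * lam_f

    sf = 0.0
    if lam_f > 0 and hasattr(phantom, "scatter_fraction_estimate"):
        sf = float(phantom.scatter_fraction_estimate())
    return RateReport(
        window=window,
        f18_singles_cps=r_f,
        i131_singles_cps=r_i,
        f18_trues_cps=trues * (1.0 - sf),
        f18_scatter_cps=trues * sf,
        f18_randoms_cps=tau * r_f * r_f,
        i131_accidental_cps=tau * r_i * r_i,
        cross_randoms_cps=2.0 * tau * r_i * r_f,
    )


def prompt_fraction_model(i131_uci: float, f18_uci: float, window,
                          scanner: ScannerModel) -> float:
    """Closed-form contamination fraction (%) for a point-source pair."""
    report = counting_rates({"I-131": i131_uci, "F-18": f18_uci},
                            window, scanner)
    return report.fraction_percent


def prompt_emission_fraction(source) -> float:
    """Contamination fraction in percent: 100 × I / (F-prompts + I).

    ``source`` may be a :class:`RateReport` or a sequence of
    :class:`Coincidence` events (any coincidence involving at least one I-131
    photon counts as contamination).  Raises if no prompts were counted.
    """
    if isinstance(source, RateReport):
        i = source.i131_accidental_cps
        f = source.f18_prompts_cps
    else:
        kinds = [c.kind for c in source]
        i = sum(k == "i131-contaminated" for k in kinds)
        f = sum(k in ("true", "scatter", "random") for k in kinds)
    total = i + f
    if total <= 0:
        raise ValueError("no prompts counted; fraction undefined")
    return 100.0 * i / total


# -- sinograms ---------------------------------------------------------------

@dataclass
class Sinogram:
    """Coincidence counts on the (angle × radial-offset) grid.

    ``counts`` is indexed ``[angle, radial]``; ``meta`` carries acquisition
    provenance (window, duration, seed, isotopes, overflow tally, ...).
    """

    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D [angle, radial]")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_angles(self) -> int:
        return self.counts.shape[0]

    @property
    def n_radial(self) -> int:
        return self.counts.shape[1]

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def copy(self, **meta) -> "Sinogram":
        return Sinogram(self.counts.copy(), {**self.meta, **meta})

    def radial_mm(self) -> np.ndarray:
        bin_mm = self.meta.get("bin_mm", 1.0)
        return (np.arange(self.n_radial) - (self.n_radial - 1) / 2.0) * bin_mm

    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * 180.0 / self.n_angles


@dataclass(frozen=True)
class Coincidence:
    """One recorded coincidence on a line of response (LOR)."""

    s_mm: float
    phi_deg: float
    kind: str            # true | scatter | random | i131-contaminated
    e1_kev: float
    e2_kev: float
    t_s: float = 0.0
    decay1: int = -1
    decay2: int = -1


def bin_sinogram(events: Sequence[Coincidence], scanner: ScannerModel,
                 **meta) -> Sinogram:
    """Histogram events onto the scanner's (φ, s) grid.

    Each LOR goes to the nearest bin; LORs outside the radial field of view
    are tallied under ``meta["overflow"]``, never silently dropped.
    Total counts are conserved: ``sum + overflow == len(events)``.
    """
    counts = np.zeros((scanner.n_angles, scanner.n_radial_bins))
    overflow = 0
    half = (scanner.n_radial_bins - 1) / 2.0
    dphi = 180.0 / scanner.n_angles
    for ev in events:
        iphi = int(round(ev.phi_deg / dphi)) % scanner.n_angles
        irad = int(round(ev.s_mm / scanner.radial_bin_mm + half))
        if 0 <= irad < scanner.n_radial_bins:
            counts[iphi, irad] += 1
        else:
            overflow += 1
    meta = {"bin_mm": scanner.radial_bin_mm, "overflow": overflow, **meta}
    return Sinogram(counts, meta)


def sample_contaminated_sinogram(trues: Sinogram, fraction_percent: float,
                                 seed=None) -> Sinogram:
    """Add a Poisson-sampled spatially uniform contamination background.

    The expected background total is ``f/(1−f) × sum(trues)`` with
    ``f = fraction/100``, so the contamination fraction of the returned
    sinogram equals ``fraction_percent`` in expectation.  ``fraction = 0``
    returns the input unchanged (fast imaging path for the near-uniform
    prompt-gamma background).
    """
    if not 0.0 <= fraction_percent < 100.0:
        raise ValueError("fraction must be in [0, 100) percent")
    if fraction_percent == 0.0:
        return trues.copy(contamination_fraction_percent=0.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = fraction_percent / 100.0
    per_bin = f / (1.0 - f) * trues.total / trues.counts.size
    bg = rng.poisson(per_bin, size=trues.counts.shape)
    return Sinogram(trues.counts + bg,
                    {**trues.meta,
                     "contamination_fraction_percent": fraction_percent})


# -- Monte Carlo path --------------------------------------------------------

_MU_WATER_511_PER_MM = 0.0096


def mu_water_per_mm(e_kev) -> np.ndarray:
    """Linear attenuation of water, 0.0096/mm at 511 keV with an approximate
    1/√E energy scaling."""
    return _MU_WATER_511_PER_MM * np.sqrt(511.0 / np.asarray(e_kev, float))


def _klein_nishina_cos(e_kev: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample Compton scattering cosθ from the Klein–Nishina angular
    distribution by rejection."""
    n = e_kev.size
    out = np.empty(n)
    todo = np.arange(n)
    a = e_kev / 511.0
    while todo.size:
        c = rng.uniform(-1.0, 1.0, todo.size)
        ratio = 1.0 / (1.0 + a[todo] * (1.0 - c))      # E'/E
        w = ratio * ratio * (ratio + 1.0 / ratio - (1.0 - c * c))
        accept = rng.uniform(0.0, 2.0, todo.size) < w  # envelope 2 ≥ max(w)
        out[todo[accept]] = c[accept]
        todo = todo[~accept]
    return out


def _rotate_about(u: np.ndarray, cos_t: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """New unit vectors at angle θ (cosθ given) from u, random azimuth."""
    n = u.shape[0]
    # orthonormal frame (a, b) ⊥ u
    helper = np.where(np.abs(u[:, [2]]) < 0.9, [[0.0, 0.0, 1.0]],
                      [[1.0, 0.0, 0.0]])
    a = np.cross(u, helper)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b = np.cross(u, a)
    psi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    return (u * cos_t[:, None]
            + (a * np.cos(psi)[:, None] + b * np.sin(psi)[:, None])
            * sin_t[:, None])


class _PointSampler:
    """Activity-position sampler for mapping-style (point source) phantoms."""

    def __init__(self, acts: dict[str, float]):
        self._acts = acts

    def sample_activity_points(self, isotope, n, rng):
        return np.zeros((n, 3))

    def water_path_mm(self, origin, direction):
        return np.zeros(origin.shape[0])


def _phantom_interface(phantom):
    if hasattr(phantom, "sample_activity_points"):
        return phantom
    return _PointSampler(_phantom_activities(phantom))


def _detect(pos: np.ndarray, direction: np.ndarray, e_kev: np.ndarray,
            window: EnergyWindow, scanner: ScannerModel,
            rng: np.random.Generator, extra_accept=None):
    """Propagate photons to the detector ring; return (accepted mask,
    hit xy, deposited blurred energy) for in-window detections."""
    r = scanner.ring_radius_mm
    dxy2 = direction[:, 0]**2 + direction[:, 1]**2
    ok = dxy2 > 1e-12
    # solve |p_xy + t d_xy| = r  (t > 0)
    pb = pos[:, 0] * direction[:, 0] + pos[:, 1] * direction[:, 1]
    pr2 = pos[:, 0]**2 + pos[:, 1]**2
    disc = pb * pb - dxy2 * (pr2 - r * r)
    ok &= disc >= 0
    t = np.where(ok, (-pb + np.sqrt(np.maximum(disc, 0.0))) /
                 np.where(ok, dxy2, 1.0), np.inf)
    z_hit = pos[:, 2] + t * direction[:, 2]
    ok &= np.abs(z_hit) <= scanner.axial_fov_mm / 2.0

    resp = _response()
    ok &= rng.random(e_kev.size) < resp.interaction(e_kev)
    if extra_accept is not None:
        ok &= extra_accept
    is_pp = rng.random(e_kev.size) < resp.photopeak(e_kev)
    deposit = np.where(is_pp, e_kev,
                       rng.uniform(0.0, 1.0, e_kev.size) * compton_edge_kev(e_kev))
    deposit = np.maximum(deposit, 1e-6)
    blurred = blur_energy(deposit, scanner, rng)
    ok &= window.contains(blurred)
    hit_xy = pos[:, :2] + t[:, None] * direction[:, :2]
    return ok, hit_xy, blurred


def _transport(phantom, pos, direction, e_kev, rng):
    """Attenuation + single Compton scatter in the subject.

    Each photon interacts in the subject's water with probability
    1 − exp(−μ(E)·path); an interacting photon is scattered exactly once
    (Compton-dominated regime), leaving with a Klein–Nishina-sampled angle
    and reduced energy; no second interaction is modelled.  The scatter
    vertex is approximated by the emission point (subject ≪ ring).
    """
    path = phantom.water_path_mm(pos, direction)
    p_int = 1.0 - np.exp(-mu_water_per_mm(e_kev) * path)
    scat = rng.random(e_kev.size) < p_int
    if np.any(scat):
        cos_t = _klein_nishina_cos(e_kev[scat], rng)
        ratio = 1.0 / (1.0 + (e_kev[scat] / 511.0) * (1.0 - cos_t))
        e_kev = e_kev.copy()
        direction = direction.copy()
        e_kev[scat] = e_kev[scat] * ratio
        direction[scat] = _rotate_about(direction[scat], cos_t, rng)
    return direction, e_kev, scat


def _f18_pair_rate_scale(window: EnergyWindow, scanner: ScannerModel) -> float:
    """Effective emission-rate multiplier making the MC pair rate match the
    configured sensitivity S_w through the simulated detection chain."""
    geo = scanner.geometric_acceptance
    p_chain = _photon_detection_prob(511.0, window, scanner)
    spec = builtin_radionuclides()["F-18"]
    return f18_sensitivity(window, scanner) / (
        spec.positron_yield * geo * p_chain * p_chain)


def simulate_coincidences(phantom, window, scanner: ScannerModel,
                          duration_s: float, seed) -> list[Coincidence]:
    """Event-level Monte Carlo acquisition (slower oracle path).

    Samples decays and photons, applies simplified subject transport,
    detection with energy blur and windowing, pairs singles within the
    timing window τ, and classifies every coincidence.  The I-131 prompt
    gammas are modelled as a temporally independent Poisson photon stream
    (no cascade time correlation), matching the purely accidental
    contamination the closed-form path describes.  Reproducible per seed.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    window = _as_window(window)
    rng = np.random.default_rng(seed)
    acts = _phantom_activities(phantom)
    geom = _phantom_interface(phantom)
    specs = builtin_radionuclides()
    geo = scanner.geometric_acceptance

    lam_f = activity_to_decay_rate(acts.get("F-18", 0.0))
    lam_i = activity_to_decay_rate(acts.get("I-131", 0.0))
    i_lines = specs["I-131"].gamma_lines
    kappa = scanner.singles_yield_scale
    m_f = _f18_pair_rate_scale(window, scanner) if lam_f > 0 else 0.0

    est_singles = duration_s * (
        2.0 * lam_f * specs["F-18"].positron_yield * m_f * geo
        + lam_i * kappa * sum(l.intensity for l in i_lines) * geo)
    if est_singles > scanner.event_cap:
        raise RuntimeError(
            f"expected ~{est_singles:.2e} singles exceeds the event cap "
            f"{scanner.event_cap:.0e}; scale down duration or activity")

    t_list, pos_list, dir_list, e_list = [], [], [], []
    decay_list, iso_list = [], []
    next_decay = 0

    if lam_f > 0:
        n_pairs = rng.poisson(lam_f * specs["F-18"].positron_yield
                              * m_f * duration_s)
        times = rng.uniform(0.0, duration_s, n_pairs)
        pts = geom.sample_activity_points("F-18", n_pairs, rng)
        z = rng.uniform(-1.0, 1.0, n_pairs)
        phi = rng.uniform(0.0, 2.0 * np.pi, n_pairs)
        s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        u = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
        ids = next_decay + np.arange(n_pairs)
        next_decay += n_pairs
        for sign in (1.0, -1.0):
            t_list.append(times)
            pos_list.append(pts)
            dir_list.append(sign * u)
            e_list.append(np.full(n_pairs, 511.0))
            decay_list.append(ids)
            iso_list.append(np.zeros(n_pairs, dtype=np.int8))  # 0 = F-18

    if lam_i > 0:
        for line in i_lines:
            n = rng.poisson(lam_i * kappa * line.intensity * duration_s)
            t_list.append(rng.uniform(0.0, duration_s, n))
            pos_list.append(geom.sample_activity_points("I-131", n, rng))
            z = rng.uniform(-1.0, 1.0, n)
            phi = rng.uniform(0.0, 2.0 * np.pi, n)
            s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
            dir_list.append(np.column_stack(
                [s * np.cos(phi), s * np.sin(phi), z]))
            e_list.append(np.full(n, line.energy_kev))
            decay_list.append(next_decay + np.arange(n))
            next_decay += n
            iso_list.append(np.ones(n, dtype=np.int8))          # 1 = I-131

    if not t_list:
        raise ValueError("phantom holds no activity")

    t = np.concatenate(t_list)
    pos = np.concatenate(pos_list)
    direction = np.concatenate(dir_list)
    e = np.concatenate(e_list)
    decay = np.concatenate(decay_list)
    iso = np.concatenate(iso_list)

    direction, e, scattered = _transport(geom, pos, direction, e, rng)
    ok, hit_xy, deposit = _detect(pos, direction, e, window, scanner, rng)

    t, hit_xy, deposit = t[ok], hit_xy[ok], deposit[ok]
    decay, iso, scattered = decay[ok], iso[ok], scattered[ok]

    order = np.argsort(t, kind="stable")
    t, hit_xy, deposit = t[order], hit_xy[order], deposit[order]
    decay, iso, scattered = decay[order], iso[order], scattered[order]

    # greedy pairing of time-adjacent singles within |Δt| ≤ τ
    tau = scanner.tau_s
    events: list[Coincidence] = []
    i = 0
    n = t.size
    while i + 1 < n:
        if t[i + 1] - t[i] <= tau:
            p1, p2 = hit_xy[i], hit_xy[i + 1]
            d = p2 - p1
            phi_deg = (math.degrees(math.atan2(d[1], d[0])) + 90.0) % 180.0
            phi_r = math.radians(phi_deg)
            s_mm = p1[0] * math.cos(phi_r) + p1[1] * math.sin(phi_r)
            if iso[i] == 1 or iso[i + 1] == 1:
                kind = "i131-contaminated"
            elif decay[i] == decay[i + 1]:
                kind = "scatter" if (scattered[i] or scattered[i + 1]) else "true"
            else:
                kind = "random"
            events.append(Coincidence(
                s_mm=float(s_mm), phi_deg=float(phi_deg), kind=kind,
                e1_kev=float(deposit[i]), e2_kev=float(deposit[i + 1]),
                t_s=float(t[i]), decay1=int(decay[i]), decay2=int(decay[i + 1])))
            i += 2
        else:
            i += 1
    return events
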