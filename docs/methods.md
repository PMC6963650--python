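# Methods

## Physical model

**Emission.**  F-18 decays by positron emission (yield 0.967); each decay
that annihilates yields two back-to-back 511 keV photons.  I-131 emits no
positrons; its PET-relevant output is the prompt single gammas at
284/364/637/723 keV with branching 6/82/7/2 %.  The therapeutic betas
(334 keV 7 %, 606 keV 90 %) are carried in the nuclide spec for bookkeeping
but deposit no detector signal: they do not escape the subject, and the
contamination mechanism is gamma-only.  A `variant="literature"` flag loads
decay-table-refined intensities (e.g. 81.5 % for 364 keV) instead of the
rounded defaults.

**Detection (semi-analytic).**  A photon of energy E reaching the ring is
detected with probability

    geometric acceptance G × interaction probability i(E) × in-window deposit
    probability w(E)

where G = z/√(z² + R²) is the solid-angle fraction of the detector band for
a centred source (defaults: ring diameter 161 mm, axial FOV 127 mm →
G ≈ 0.62), i(E) and the photopeak fraction p(E) come from a small packaged
lookup for an LSO-like block (linear interpolation in energy), and w(E)
combines the Gaussian-blurred photopeak with a flat Compton-continuum
approximation on [0, 2E²/(511+2E)], also blurred.  Energy resolution is
11 % FWHM at 511 keV, scaled as FWHM(E) = 0.11·√(511·E) keV (constant
fractional resolution in 1/√E).  Windows are half-open [low, high) keV.

**Coincidence rates.**  Pairs are accepted when |t₁ − t₂| ≤ τ with
τ = 3.432 ns (documented Inveon coincidence window; configurable).  Under
that convention the accidental-coincidence rate between two independent
singles streams is 2τR₁R₂ and *within* one stream τR².  F-18 prompt
coincidences are S_w·λ_F with the window sensitivities S_w fixed at the
characterized values (7.0/7.3/5.8/6.0 % for 350–650/350–750/450–650/450–750
keV); other windows scale the semi-analytic pair-detection value anchored at
350–650 keV.

**The contamination fraction.**  Contaminated coincidences are accidental
pairings among the I-131 in-window singles, rate τ·(κ_w·λ_I)².  The
fraction f = I/(F + I) therefore has odds quadratic in the I-131 activity.
The two isotopes' rates are evaluated **independently** (as in
single-isotope rate characterization); cross-isotope accidentals 2τ·R_I·R_F
are reported separately and excluded from f.  The packaged calibration
surface is quadratic down to 10 µCi, which is only consistent with that
per-isotope convention — a cross term linear in activity would put ~3 %
contamination at 100 µCi instead of the tabulated 1.45 %.

**Calibration.**  The single free constant κ (I-131 singles-yield scale)
absorbs detector efficiency and timing-window uncertainty.  It is fixed
once by matching the closed-form fraction at 300 µCi I-131 + 100 µCi F-18
in 350–650 keV to the packaged table (11.64 %); κ ≈ 1.95 relative to the
uncalibrated lookup chain.  All other activities (1 µCi – 10 mCi) and all
other windows are predictions; across the 100–1000 µCi column the model
stays within 1.1 percentage points of the table, and the 450–650 keV
fraction at 1 mCi comes out ~200× below the 350–650 keV one, reproducing
the near-immunity of the narrow window.

**Cascade decorrelation (model assumption).**  The 364 and 637 keV gammas of
one I-131 decay are physically simultaneous, but the calibration surface
shows no linear-in-activity component, so the in-window I-131 singles
stream is modelled as a temporally independent Poisson photon stream: the
Monte Carlo assigns each prompt gamma an independent emission time, and no
cascade (same-decay) coincidences are formed.  Angular correlation is
likewise ignored (prompt-gamma directions are isotropic and independent).
Because κ and the F-18 pair-rate anchor exceed unity, both are applied as
effective emission-rate multipliers (Poisson amplification), which is
exactly equivalent under this independent-singles model.

## Monte Carlo path

Decay counts are Poisson in activity × duration; emission points are sampled
proportionally to the activity map; directions are isotropic.  Transport in
the subject is simplified: a photon interacts in water with probability
1 − exp(−µ(E)·path) (µ = 0.0096/mm at 511 keV, ∝ 1/√E), and an interacting
photon Compton-scatters exactly once with a Klein–Nishina-sampled angle and
the corresponding energy loss; the scatter vertex is approximated by the
emission point (subject ≪ ring radius), and no second interaction is
modelled.  Detection follows the same lookup chain as the analytic path
(interaction, photopeak vs continuum deposit, Gaussian blur, window), which
is what makes the 3σ Monte-Carlo-vs-closed-form agreement a meaningful
consistency check rather than a fit.  Singles are greedily paired in time
order within τ and classified: any coincidence involving an I-131 photon is
contamination; same-decay F-18 pairs are trues (or scatter if either photon
scattered); the rest are randoms.  An event cap (default 5×10⁶ expected
singles) guards against runaway memory and asks for a shorter duration.

## Phantoms and imaging

Imaging is 2-D, single direct transaxial slice, matching slice-wise FBP.
The NEMA NU4 image-quality phantom uses the standard 30 mm body (uniform
region 15 mm long) with the two printed cold chambers (15 mm × 8 mm bore;
one air, one non-radioactive water) placed at x = ±7 mm; the SOR VOIs are
4 mm × 7.5 mm cylinders centred in the chambers (50 % of the bore, within
the ≤75 %-of-diameter rule) plus a uniform-region VOI in the same slice.
The mouse phantom is a stylized ellipsoid (12.5×12.5×35 mm semi-axes) with
uniform background uptake, a subcutaneous spherical tumor of the requested
volume (hot shell, default 3× background; necrotic core at half the radius,
default cold), and the caliper formula width²×length×0.4 for volumes; it
replicates the in-vivo setting qualitatively, not anatomically.  Body mass
for SUV defaults to 20 g (not specified by the source protocol;
configurable).

Phantoms are strict hierarchies of primitives (later primitives override —
are carved into — earlier ones; partial overlap unsupported).  Voxelization
(default 0.4 mm) anti-aliases with 4×4 sub-voxel sampling, conserving the
slice's areal activity to ≲0.1 %.  Forward projection uses the Radon
transform on the voxel grid resampled onto the scanner's 128 × 0.8 mm
radial bins × 160 angles; FBP uses the matched inverse (ramp filter at
Nyquist by default, Hann optional).  Attenuation correction multiplies each
bin by exp(+∫µ dl) from the phantom's media (an analytic stand-in for a
transmission scan).  Normalization and dead-time are identity placeholders
with logged provenance.  VOI membership is voxel-centre-in-solid, with no
partial-volume weighting, consistent with quantification that applies no
partial-volume correction.

## The correction

Given an uncorrected sinogram and a fraction f (from the packaged table —
default —, the published linear model max(0, 0.06·A − 6.72) %, the
calibrated rate model, or a user value):

1. per angle, object support = radial span between the first and last bin
   exceeding the per-angle baseline (profile minimum) by 10 % of the range
   above it (threshold configurable; baseline-relative so that a strong
   flat background does not swallow the tails);
2. the background level is fitted from the out-of-support bins — one global
   mean (`tail-uniform`) or per-angle means smoothed along the angle axis
   (`tail-gaussian`);
3. the prompt-gamma estimate is the background *shape* normalized so its
   total equals f × Σ(uncorrected) — this makes the subtracted mass equal
   the contamination share of recorded prompts.  The literal reading
   (background × f, no normalization) is available via `eq1_literal=True`;
   the two coincide when the tails measure the contamination level exactly;
4. subtraction, with negative bins clamped to zero and counted (counts
   cannot be negative; no rescaling of other bins).  An optional
   `scatter_share` of the background is subtracted as residual scatter
   (default 0: scatter handling belongs to the upstream correction chain).

Degenerate inputs: an all-zero sinogram yields a zero background; fraction 0
is the exact identity; a sinogram whose support spans every radial bin has
no tails and raises.  Bin-wise, corrected + prompt estimate + scatter share
= uncorrected up to the clamped mass, checked exactly in the tests.

## The spill-over-ratio study (synthetic validation)

The FDG-only gold standard and the contaminated acquisition share one
Poisson realization of the expected NU4 prompts (trues plus a smooth,
object-driven scatter component: trues convolved radially with a 15 mm σ
Gaussian, scaled to a 15 % pair scatter fraction — a typical preclinical
value; without it the cold-chamber baseline would be ≈ 0 and a *relative*
SOR comparison meaningless).  The contaminated arm adds a Poisson uniform
background with expected total f/(1−f) × prompts, f = 12 % — the
contamination level at 300 µCi I-131 with 100 µCi FDG.  Because the NEMA
cold-chamber VOI is volumetric (4 mm ⌀ × 7.5 mm) and reconstruction is
slice-wise, the study acquires one sinogram of ~2×10⁶ counts per 0.4 mm
slice spanning the VOI (19 slices) and pools the VOI over slices.  Both
arms are FBP-reconstructed identically (ramp); the reported number is
100·|SOR_corrected − SOR_gold|/SOR_gold.

What passing shows — and does not.  The generator emulates Poisson counting
noise, a smooth scatter background and a *uniform* contamination field; it
does not emulate block-detector effects, dead time, depth of interaction,
sinogram normalization structure, or any deviation of the prompt-gamma
background from uniformity.  Recovery of the gold-standard SOR to <5 %
therefore validates the estimation-and-subtraction machinery under the
model's own assumptions, not detector-level fidelity; the scanner-measured
SORs and in-vivo SUVs of the motivating experiment are not reproducible at
desk scale and are covered only qualitatively by these synthetic analogues.

## Numerical choices

* Continuum in-window masses use 64-point midpoint quadrature with blur.
* Sinogram binning: nearest bin in (φ, s); out-of-FOV LORs go to an
  overflow tally, never silently dropped.
* FBP resamples the 0.8 mm radial bins onto the 0.4 mm output grid by
  linear interpolation before filtering; output is divided by the voxel
  size so a forward-projected map reconstructs in its own units
  (round-trip NRMSE ≈ 2 % on the NU4 phantom).
* Randomness: every stage takes a `numpy` Generator or integer seed; the
  multi-slice study derives per-slice substreams via `SeedSequence.spawn`;
  seeds are recorded in all output headers.
* OLS fits via `scipy.stats.linregress`; constant-y input defines R² = 0.
* Percent difference uses the gold standard in the denominator.

## Known limitations

* The closed-form fraction model is calibrated to a full-transport Monte Carlo reference surface;
  absolute counting rates (kcps curves) are qualitative only.
* Single-scatter, emission-point-vertex transport underestimates broad
  scatter tails; the tail-based background estimator is the desk-scale
  stand-in for a single-scatter-simulation chain.
* 2-D direct-slice geometry; no 3-D acquisition/rebinning, no iterative
  reconstruction.
* The published linear fraction model's printed slope (0.06 %/µCi) is not
  the exact OLS refit of the calibration column (≈ 0.068 %/µCi); the
  packaged constants keep the printed values, and the refit is exposed via
  `linear_fit`.
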