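# petprompt

Dual-isotope small-animal PET simulation and **I-131 prompt-emission
correction** for ¹⁸F-FDG imaging during ¹³¹I therapy.

## The problem

¹⁸F-FDG PET is the workhorse for monitoring tumor response, including after
¹³¹I radioimmunotherapy (e.g. ¹³¹I-rituximab in lymphoma models).  But ¹³¹I
emits prompt single gammas — 284 keV (6 %), 364 keV (82 %), 637 keV (7 %),
723 keV (2 %) — and the wide energy windows used in small-animal PET
(350–650 or 350–750 keV) accept them.  Two such singles recorded within the
coincidence timing window τ form an *accidental* coincidence that carries no
annihilation information: because the prompt-gamma direction is uncorrelated
with the 511 keV pair, these events spread nearly uniformly over the
sinogram, inflating cold-region values, spill-over ratios and SUVs.

This package provides, for users of preclinical PET who must scan FDG soon
after a therapeutic ¹³¹I administration:

* a **rate model** of the contamination.  With ¹³¹I in-window singles rate
  `R_w = κ_w λ_I`, the contaminated coincidence rate is the accidental
  closed form `τ R_w²`, while FDG contributes prompts at `S_w λ_F` (window
  sensitivity `S_w`, e.g. 7.0 % for 350–650 keV).  The **prompt-emission
  fraction** is

  `f = 100 × I-coincidences / (F-prompts + I-coincidences)` ,

  whose odds therefore grow *quadratically* with ¹³¹I activity.  The single
  free scale κ is calibrated once against the packaged fraction table at
  (300 µCi, 350–650 keV); every other activity and window is a prediction.
* an **event-level Monte Carlo** (decay sampling, simplified transport with
  attenuation and single Compton scatter, energy-blurred detection, time
  pairing, event classification) serving as an independent cross-check of
  the closed form.
* the **correction**: estimate the smooth background from the sinogram tails
  (object support by thresholding each angle's radial profile), scale it so
  its total equals `f` × recorded prompts, subtract, clamp negatives:

  `prompt-gamma sinogram = background shape × f × Σ(uncorrected)` .

* digital phantoms (NEMA NU4 image quality, stylized tumor-bearing mouse),
  parallel-beam forward projection, FBP reconstruction, analytic attenuation
  correction, and the quantification metrics (spill-over ratio, SUVmax,
  contrast, percent difference).

## Worked example

```python
import petprompt as pp

scanner = pp.calibrate_scanner()          # one-point kappa calibration
for a in (100, 300, 1000):
    f = pp.prompt_fraction_model(a, 100.0, "350-650", scanner)
    print(f"I-131 {a:>5d} uCi + F-18 100 uCi, 350-650 keV: fraction {f:5.2f} %")

from petprompt.studies import nu4_sor_study
r = nu4_sor_study(seed=1, fraction_percent=12.0)
print(f"SOR gold {r.sor_gold:.2f} %  uncorrected {r.sor_uncorrected:.2f} %  "
      f"corrected {r.sor_corrected:.2f} %")
print(f"percent difference vs gold: corrected {r.pct_diff_corrected:.2f} %, "
      f"uncorrected {r.pct_diff_uncorrected:.2f} %")
```

prints

```
I-131   100 uCi + F-18 100 uCi, 350-650 keV: fraction  1.44 %
I-131   300 uCi + F-18 100 uCi, 350-650 keV: fraction 11.64 %
I-131  1000 uCi + F-18 100 uCi, 350-650 keV: fraction 59.41 %
SOR gold 5.01 %  uncorrected 5.52 %  corrected 4.97 %
percent difference vs gold: corrected 0.89 %, uncorrected 10.28 %
```

Reading: at 300 µCi of ¹³¹I alongside 100 µCi of FDG roughly 12 % of
recorded coincidences are contamination; at 1 mCi the scan is more
contamination than signal.  On the simulated NU4 phantom a 12 % uniform
contamination shifts the water cold-chamber spill-over ratio by ~10 %
relative to the FDG-only gold standard; after tail-based, fraction-scaled
subtraction the difference drops below 1 % — i.e. the corrected scan
quantifies like a clean FDG scan.

A fraction-vs-activity line fit (the calibration table's 350–650 keV column
over 100–1000 µCi) is available as `petprompt fit-fraction` and yields an
intercept of ≈ −6.7 % and R² ≈ 0.99.

## Command line

`petprompt rates | simulate | correct | recon | metrics | fit-fraction |
fixtures` — thin wrappers over the library.  Windows are `LOW-HIGH` in keV
(half-open), activity ranges `START:STOP[:STEP]` in µCi; every artifact is
written with a text header carrying its provenance (seed, window, config).

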