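# Methods

This note documents the models, conventions and numerical choices behind
`hybridose`, and what the synthetic validation does and does not
demonstrate about real patient data.

## Dosimetry chain

### Conjugate-view planar quantification

Activity per region and time point is estimated from paired
anterior/posterior count rates as `A = sqrt(I_A·I_P/T)·f/C`, after two
corrections applied per view:

* **DEW scatter**: the scatter contribution in the photopeak window is
  estimated as `k·I_scatter·w`, where `w` is the keV width ratio of the
  photopeak to the scatter window. The packaged protocol windows give
  `w = (0.20·74.6)/(0.15·69.4) ≈ 1.433` for ¹⁶¹Tb and
  `w = (0.20·208)/(0.15·187) ≈ 1.483` for ¹⁷⁷Lu. The multiplier `k`
  defaults to 1 (the standard DEW form) and is configurable, since it is
  a camera-specific property.
* **Background**: the per-pixel rate in a nearby background ROI is
  scaled to the organ ROI pixel count and subtracted.

Negative corrected rates clamp to zero with a `CLAMPED_COUNTS` warning
rather than aborting: late-time, low-count frames are a routine
occurrence in patient runs, and a hard error there would discard the
rest of the study. `T` is the per-region blank/transmission photon
transmission; per-pixel attenuation maps are out of scope (per-region
`T` is the resolution the ROI-level chain consumes). The source
self-attenuation factor `f` defaults to 1 (thin source); the uniform
slab correction `f = (μt/2)/sinh(μt/2)` is provided opt-in.

### Segmentation

Organ delineation inside a manually drawn boundary uses threshold
segmentation: keep pixels ≥ `threshold_fraction` × (maximum inside the
boundary). Lesion volumes use an SUVmax isocontour fraction restricted
to [0.20, 0.40]. More elaborate adaptive-Bayesian segmentation exists in
clinical packages; the threshold rule is deliberately simple,
deterministic, and sufficient for the ROI-level pipeline.

### SPECT quantification and hybrid rescaling

SPECT VOI counts divide by the camera calibration factor and then by a
recovery coefficient `RC(v)`. Two forms are supported: a tabulated curve
(linear interpolation on a log-volume axis; volumes below the table use
the smallest tabulated RC with a warning) and the parametric
`RC(v) = v/(v + v50)`. The packaged default, `v50 = 2 mL`, is a
*synthetic* curve chosen for plausibility (RC ≈ 0.83 at 10 mL, ≈ 0.99 at
300 mL); real deployments must measure their own recovery curve, which
is a scanner/reconstruction property.

The planar time-activity curve is rescaled by a single SPECT point: the
planar monoexponential fit is evaluated at the SPECT time and all planar
samples multiply by `SPECT / prediction`. This removes multiplicative
planar biases (calibration, attenuation-path error) while retaining
planar temporal sampling — the purpose of the hybrid method. The SPECT
time must lie within the planar window ± 12 h.

### Kinetics

Fits minimise `Σ wᵢ (Aᵢ − A0·e^{−λtᵢ})²` over `A0 > 0, λ > 0` with
`scipy.optimize.least_squares` (trust-region reflective, xtol = ftol =
gtol = 1e-14), initialised from the unweighted log-linear regression —
which is already exact for two points, making the two-point closed form
hold to machine precision. Default weights are `wᵢ = 1/Aᵢ`
(Poisson-like variance for count-derived activities); `uniform` and
user-σ (`1/σᵢ²`) are available, and the choice is recorded in the fit
result. Non-decaying data are flagged `NON_DECAYING` but still fitted;
a fitted λ below the physical decay constant raises
`LAMBDA_BELOW_PHYSICAL` (biological accumulation) as a warning, not an
error.

Integration runs from t = 0 using the fitted curve — no uptake-phase
triangle. A monoexponential fitted to points from 24 h onward and
integrated analytically implies exactly this convention;
`TIAC = (A0/100)·e^{−λ·t_start}/λ` with `t_start = 0` by default.

### Self-dose model

Absorbed dose per administered activity is computed for unit-density
spheres (lesions, salivary glands: parotid 25 g, submandibular 12.5 g
per ICRP 89) and reference organs (kidneys 310 g, liver 1800 g by
default, overridable per patient):

* electron component: `TIAC·3600·E_e·q/m`, with `E_e` the mean β energy
  plus any configured conversion/Auger energy (φ_e = 1, appropriate for
  sub-mm electron ranges at organ scale), `q = 1.602176634e−16 J/keV`
  (exact SI), `m` in kg; × 1e9 for Gy/GBq.
* photon component: per line, `TIAC·3600·E_γ·yield·q·φ_p(m, E_γ)/m`,
  with the mean-chord absorbed fraction
  `φ_p = 1 − exp(−μ_en(E)·(4/3)·r)` and `μ_en` interpolated log-log from
  the packaged NIST water table (valid 20–2000 keV; lines below 20 keV
  are dropped by default as locally absorbed).

**Known limitation.** The mean-chord expression is the
exponential-of-mean over μ-random chords of the sphere; it agrees with
the chord-averaged absorption (the Monte-Carlo chord-sampling oracle in
the test suite) to < 1 % in the optically thin regime relevant here, but
it is *not* interior-emission photon transport — for a uniform internal
source the mean escape path is 3r/4, not the chord mean 4r/3, so the
model overstates photon self-absorption by up to ~2× at small μr. It
also neglects cross-organ photon dose and scatter buildup. Since the
photon component is a few percent of the electron component for these
nuclides, the package treats absolute organ doses as model-dependent and
focuses comparisons on ratios (inter-nuclide factors, TI, rTI), which
the approximation largely cancels out of. Reproducing the S-value
libraries of clinical codes (OLINDA/EXM, IDAC) is explicitly not
attempted. The packaged `extra_electron_keV` is 0 for both nuclides —
the conversion/Auger contribution central to the ¹⁶¹Tb rationale is a
user-supplied datum, not a hard-coded guess.

### Cohort metrics

* Cohort cells are mean ± **population** SD (denominator n). This is the
  convention that reproduces the packaged six-patient reference table's
  printed SD cells; the sample (n−1) convention does not.
* Rounding happens only at the presentation layer: 3 d.p. for doses,
  2 d.p. for ratios, half away from zero. Internal values stay at full
  precision. (One consequence: the parotid ¹⁷⁷Lu mean of the packaged
  per-patient values is 0.3335 and the ¹⁶¹Tb one 0.3675, which present
  as 0.334 and 0.368 under this rule while the reference table prints
  0.333 and 0.367 — exact-half edges at 3 d.p. that round-to-even would
  resolve the other way.)
* Per-patient mean tumor dose is the unweighted mean over that patient's
  analyzed lesions (no volume weighting).
* TI = mean tumor dose / organ-at-risk dose per patient and nuclide;
  rTI = TI(¹⁶¹Tb)/TI(¹⁷⁷Lu). Both are invariant under any common
  rescaling of one patient's doses, so they are insensitive to
  calibration errors that act multiplicatively per study.
* PCWG3 classification uses strict inequalities: PD for ΔPSA > +25 %,
  PR for ΔPSA < −50 %, SD otherwise; ±boundary values are SD.

## Synthetic phantom

The generator emulates the acquisition design the chain was built for:
three planar time points at 24/48/96 h post injection, one SPECT
estimate per region, and monoexponential washout
`A(t) = A0·e^{−(λ_bio+λ_phys)t}` per region.

Forward model per region/time: primary geometric counts
`P = C·A_MBq·√T` with `T = exp(−2μ·depth)`; the photopeak expectation
adds `k·w·SF·P` of scatter (so the DEW subtraction of the recorded
scatter-window counts `SF·P` removes it exactly) and the pixel-scaled
background; Poisson draws are taken per window and view. SPECT emits
post-reconstruction activity degraded by `RC(v)` plus Gaussian noise
(default σ = 2 % of the true activity). A seed is mandatory; identical
specs give identical datasets.

Defaults describe a realistic PSMA-617 patient: injected activity
6.4 GBq; kidneys 2.64 %IA with λ_eff ≈ 0.021 h⁻¹, liver 3.72 %IA,
parotid 0.53 %IA, submandibular 0.41 %IA, one 10-mL lesion with ~46 h
effective half-life; effective attenuation μ = 0.15 cm⁻¹
(water-equivalent at these photon energies), scatter fraction 0.2,
diffuse background 5 %IA spread over a nominal 10⁴-pixel body area, and
a planar calibration of 100 counts/MBq. Uptake fractions plus background
are validated to stay within 100 % of the injected activity.

`true_dose` is the closed-form oracle: `TIAC = (A0/100)/λ_eff` pushed
through the same self-dose model, so the noiseless pipeline must agree
to numerical precision (observed ≤ 1e−15 relative) and noisy runs can be
scored for parameter recovery. Validation sizes: 200 Poisson replicates
with the calibration raised to 10⁴ counts/MBq — the smallest power of
ten putting every region×time expected photopeak count above 10⁴ —
give median |error| in A0 and λ of ~0.3 %, far inside the 5 % banner.

**What this does not show.** The phantom is the chain's own forward
model run backwards, so passing tests demonstrate internal consistency,
correct inversion and noise robustness — not clinical accuracy. Real
data add ROI misplacement, organ overlap, co-registration error,
non-monoexponential kinetics, septal penetration of low-energy ¹⁶¹Tb
photons, and recovery curves that differ from the packaged parametric
stand-in. The optional 2D image mode paints rectangular regions on a
256×1024 grid (4.66 mm pixels) purely so segmentation operators have a
surface to run on; it is not an anthropomorphic phantom.

## Design choices

* Region-level (not pixel-level) planar simulation is the default: the
  dosimetry consumes ROI-level counts, and pixel realism would not
  change any downstream quantity.
* SPECT reconstruction (OSEM, collimator response) is not simulated or
  modeled; the recovery curve plus additive noise is the interface.
* λ is not constrained to ≥ λ_phys: such fits are data-quality warnings,
  since truncating them would bias TIACs silently.
* Stages communicate via delimited text tables with documented columns;
  every output carries a SHA-256 configuration hash (excluding output
  location and verbosity) so that identical configurations are
  verifiably identical runs.
* Wilcoxon-type significance testing across lesions is out of scope:
  the packaged fixtures carry organ-level doses only, and lesion-level
  inference belongs to study analysis, not the dosimetry chain.
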