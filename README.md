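# hybridose

Hybrid planar/SPECT MIRD dosimetry for radioligand therapy, built around
the head-to-head comparison of ¹⁶¹Tb- and ¹⁷⁷Lu-labeled PSMA-617 in
metastatic castration-resistant prostate cancer (mCRPC). The package
takes conjugate-view whole-body scintigraphy counts through to organ and
lesion absorbed doses per administered activity (Gy/GBq), therapeutic
indices and PCWG3 biochemical response — and ships a synthetic phantom
generator with closed-form ground truth so the entire chain is testable
end to end.

It is aimed at medical physicists and researchers in quantitative
nuclear-medicine imaging who want a transparent, scriptable
implementation of the classic hybrid dosimetry workflow rather than a
black-box clinical tool.

## The model

**Planar quantification (conjugate-view method).** For each region ROI
at each time point, anterior/posterior photopeak count rates are
scatter-corrected with the dual-energy-window (DEW) estimate
`I = I_peak − k·I_scatter·w` (with `w` the keV width ratio of the two
windows), background-corrected by the per-pixel background scaled to the
ROI pixel count, and converted to activity

```
A = sqrt(I_A · I_P / T) · f / C
```

with `T` the blank/transmission-scan photon transmission through the
body, `f` an optional slab self-attenuation factor and `C` the planar
calibration factor.

**Hybrid rescaling and kinetics.** The serial planar activities (days 1,
2 and 4 post injection, in % injected activity) are fitted by weighted
least squares to a monoexponential `A(t) = A0·exp(−λ_eff·t)`; a single
quantitative SPECT estimate — calibrated and corrected by a
volume-dependent recovery coefficient `RC(v)` — rescales the planar
curve. The time-integrated activity coefficient follows analytically:

```
TIAC (h) = (A0 / 100) / λ_eff
```

**Sphere-model self-dose.** Electrons (mean β plus any configured
conversion/Auger energy) deposit locally (φ_e = 1); each photon line is
absorbed with the mean-chord fraction φ_p = 1 − exp(−μ_en(E)·(4/3)·r)
for a unit-density sphere of the region mass. Doses are reported in
Gy/GBq (numerically mGy/MBq). ¹⁶¹Tb (T½ = 6.906 d, mean β 154 keV,
γ 74.6/48.9 keV) and ¹⁷⁷Lu (6.647 d, 133 keV, γ 208.4/112.9 keV) are
packaged.

**Comparison metrics.** The therapeutic index TI = mean tumor dose /
organ-at-risk dose is computed per patient and nuclide; rTI =
TI(¹⁶¹Tb)/TI(¹⁷⁷Lu) > 1 indicates energy deposition favoring the
tumor under ¹⁶¹Tb. PSA changes classify per PCWG3: PD for an increase
> 25 %, PR for a decrease > 50 %, SD otherwise. Cohort cells are
mean ± population SD.

## Worked example

The packaged six-patient cohort fixture (four organs, both nuclides, plus
the per-patient PSA changes) drives the report command:

```
$ hybridose report
Absorbed dose per administered activity, mean ± SD (Gy/GBq):
  kidneys        Lu177: 0.545 ± 0.231
  kidneys        Tb161: 0.643 ± 0.247
  liver          Lu177: 0.103 ± 0.057
  liver          Tb161: 0.148 ± 0.080
  parotid        Lu177: 0.334 ± 0.194
  parotid        Tb161: 0.368 ± 0.198
  submandibular  Lu177: 0.285 ± 0.180
  submandibular  Tb161: 0.372 ± 0.188
Ratio of cohort means (Tb161/Lu177):
  kidneys        1.18
  liver          1.44
  parotid        1.10
  submandibular  1.30
PCWG3 biochemical response after one Tb-161 cycle:
  PR: 1
  SD: 3
  PD: 2
```

Kidney doses are ~18 % higher for ¹⁶¹Tb, parotid ~10 % — the price of
its extra low-energy emissions in normal organs — while one of six
patients reached partial biochemical remission after a single cycle.

The full simulation-backed chain (synthetic phantom → conjugate-view
quantification → SPECT rescaling → monoexponential fit → sphere-model
dose):

```
$ hybridose dose --seed 42 --out run_out
       region nuclide   tiac_h  dose_Gy_per_GBq  electron_component  photon_component
      kidneys   Tb161 1.273715         0.371848            0.364959          0.006889
     lesion_1   Tb161 0.663949         5.935548            5.897505          0.038043
        liver   Tb161 1.681922         0.085596            0.082998          0.002599
      parotid   Tb161 0.196910         0.705670            0.699617          0.006052
submandibular   Tb161 0.148097         1.059665            1.052371          0.007294
```

TIACs and doses here are for the default phantom (kidneys 2.64 %IA with
λ_eff ≈ 0.021 h⁻¹, a 10-mL lesion with ~46 h effective half-life, ...);
electron self-dose dominates, as expected for these β-emitters.
Per-stage artifacts (`planar_activity.csv`, `fits.csv`, `doses.csv`,
`warnings.csv`) land in `run_out/`, each stamped with the configuration
hash.

Library use mirrors the CLI:

```python
from hybridose import phantom, pipeline

cfg = pipeline.RunConfig(nuclide="Tb161", seed=1, out_dir="run_out")
doses = pipeline.run_dosimetry(cfg)
```

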