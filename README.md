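# aquanmr

Targeted metabolite quantification for 1D ¹H NMR spectra that contain broad
background signals and baseline distortions — the situation typical of
minimally prepared biological samples such as plant root exudates, where
unknown macromolecules (plausibly lipids) put wide humps under the sharp
metabolite lines.

The package is written for NMR metabolomics practitioners who have binned,
phase-corrected 1D spectra and a panel of pre-identified metabolites, and who
want absolute concentrations quickly and reproducibly without curve fitting
every spectrum. It combines two stages into one automated pipeline:

1. **Baseline correction** by adaptive iteratively reweighted penalised least
   squares (airPLS). The Whittaker smoother finds the baseline `z` minimising

   `Σᵢ wᵢ (xᵢ − zᵢ)² + λ Σᵢ (Δ² z)ᵢ²`

   and the airPLS outer loop re-weights points so that signal regions
   (`xᵢ > zᵢ`) are excluded while the fit settles onto the broad background.
   The stiffness λ (1–1e9, default 1e7) is the only parameter that needs
   tuning, and it can be overridden per ppm region (e.g. a more flexible
   λ = 1e6 over a crowded methyl region, a stiffer λ = 1e8 under a broad
   multiplet that a flexible baseline would eat).

2. **Single-reporter quantification** (the AQuA strategy). Each metabolite is
   modelled as a sum of Lorentzians; one reporter signal per metabolite is
   picked as the maximal bin in its chemical-shift window. With picked
   heights `h` and the interference matrix
   `A[m,k] =` (modelled 1 mM intensity of compound *k* at compound *m*'s
   picked position), concentrations follow from one linear solve
   `h = s·A·c`, where the spectrum-to-library scale `s` comes from the
   internal standard (DSS at known concentration, solved inside the same
   system so its own tail interferences are corrected too). Unknown
   interfering signals are carried as single-Lorentzian entries: solved for,
   never reported.

Around the core, the package ships the evaluation machinery needed to
validate such a pipeline when no ground truth exists in real spectra: a
background extractor (spike detection → depletion → three-level smoothing,
yielding background models A/B/C of decreasing roughness), a 3 × 7
simulation-study harness, a spike-in study harness, and seeded synthetic-data
generators for all of it.

## Worked example

`examples/05_spikein_study.py` spikes five metabolites over 10–3200 µM both
into a synthetic complex matrix (quantified with baseline correction) and
into clean blanks (quantified without), then regresses one arm on the other:

```
metabolite      max µM   slope       R² rel.intercept % mean diff %
asparagine        1600   1.002   1.0000           0.016         0.5
gaba               400   0.982   0.9999           0.316         2.2
tartaric_acid      800   0.983   0.9999           2.663        15.7
threonine          160   0.981   0.9999          -1.124         8.7
xylose            3200   0.986   1.0000           0.025         1.2
```

A slope of one with zero intercept would mean the baseline stage introduces
no bias at all; slopes within ~2% and R² > 0.999 show the two pipelines
agree across two and a half decades of concentration. The intercept is also
reported as a percentage of the highest spiked concentration so metabolites
with very different ranges can be compared. Mean percent differences are
largest for the metabolites spiked at the lowest concentrations, where any
residual baseline error weighs most.

The other example scripts demonstrate baseline correction with a region λ
map (`01`), full-panel quantification against known truth (`02` — all 24
targets within 10% under the default study conditions), background-model
extraction (`03`) and the 21-spectrum simulation study (`04`).

A thin command line mirrors the library:
`aquanmr correct|quantify|backgrounds|simulate|spikein|synth --help`.

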