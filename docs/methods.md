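# Methods

This note records the models, parameter choices and numerical decisions
behind `aquanmr`, and what the synthetic studies do and do not demonstrate.

## Spectrum model

A spectrum is a uniformly binned intensity vector on a segmented ppm axis.
Bins are half-open `[start + i·w, start + (i+1)·w)` with centres at
`start + (i+0.5)·w`; the canonical layout is two segments, −0.50–4.68 and
4.98–10.00 ppm at `w = 0.0002` ppm (25 900 + 25 100 = 51 000 bins), with the
water region represented as a true gap — baseline fitting and background
extraction run per segment and never bridge the suppressed solvent signal.
Whether real binning anchors bin edges or centres at −0.50 ppm is a
convention; this package anchors edges at the segment start. Conversions use
`Hz = ppm × spectrometer frequency in MHz` (600 MHz default). Linewidths are
stored in Hz so a library transfers across field strengths.

Line-shape quality control measures the full width at half maximum of the
internal-standard singlet by linear interpolation between the two
half-height bin crossings; the check passes at ≤ 1.20 Hz. No parabolic apex
refinement is attempted: at 0.0002 ppm/bin the interpolation error is below
the tolerance the check needs.

## Baseline model (airPLS)

The Whittaker smoother minimises `Σ wᵢ(xᵢ−zᵢ)² + λ Σ (Δ^d z)²` via the
banded SPD system `(W + λDᵀD) z = Wx`, solved with a symmetric banded
factorisation in O(n); the `DᵀD` bands are cached per (length, order). The
airPLS loop (difference order d = 2, max 20 iterations) sets `wᵢ = 0` where
the residual `dᵢ = xᵢ − zᵢ ≥ 0` and `wᵢ = exp(t·|dᵢ|/dssn)` where `dᵢ < 0`
(`dssn` = total negative-residual mass, exponent capped at 30 for
conditioning), and stops when `dssn < 0.001·Σ|x|`.

The cited algorithm's "weight exception proportion" (wep = 0.1) and
"asymmetry parameter" (p = 0.05) are implemented as an endpoint rule: the
first and last `⌈wep·n⌉` points of each fitted stretch never receive zero
weight — their weight is floored at `p` on every reweighting — anchoring the
baseline at the stretch ends. This is a documented interpretation of
parameters whose exact mechanics are not published alongside their names;
both are configurable.

λ is the scientifically meaningful parameter: too high and the baseline
misses broad humps, too low and it climbs into genuine signals. A
`RegionLambdaMap` re-runs airPLS with a local λ on each listed region
extended by 25 bins (0.005 ppm) per side and replaces the default baseline
inside the region, linearly cross-faded over the margin so no step artefact
appears. A region whose λ equals the default is skipped — the refit would be
identical by definition. Corrected intensities are never clipped at zero;
clipping would bias reporter heights.

Two deterministic side effects of the baseline stage are worth knowing.
First, because a sum of Lorentzians is strictly positive everywhere, the
fitted baseline absorbs a sliver of the inter-peak tail envelope even over a
zero background; on the synthetic 24 + 4 panel this perturbs recovered
concentrations by up to a few percent, concentrated in the crowded
0.93–0.97 ppm cluster. Second, the smoother can undershoot slightly beside a
tall neighbour, inflating an adjacent reporter by a similar margin. Both
effects are proportional (they move regression slopes, not intercepts) and
both vanish when the baseline stage is bypassed, which is why the blank arm
of spike-in studies — and the exact-recovery identity test — run without it.

## Quantification model

Each library entry is a sum of Lorentzians
`c · Σⱼ hⱼ γⱼ²/((δ−δ₀ⱼ−o)²+γⱼ²)`, `γⱼ = FWHMⱼ/2` in ppm, linear in the
concentration `c` and translatable by a per-entry offset `o`. One reporter
window per entry defines picking: the maximal bin in the window, ties broken
toward the nominal centre, with an *edge* flag when the maximum sits on the
window border or is non-positive (unlocalisable).

The interference matrix evaluates every entry's closed-form model at every
picked position, each entry translated by its own picked offset (alignment
to inter-spectral position variation); entries with the edge flag contribute
at their nominal positions instead. The internal standard (DSS at 0.29 mM)
is a row/column of the same system, so the intensity scale
`s = (solved DSS response)/0.29 mM` is itself corrected for tail
interference from the panel — the plain height-ratio calibration
(`calibrate_scale`) is retained as a standalone estimator but carries a
~1e-5 relative bias from far-field tails that the in-system route removes.
Concentrations come from one direct solve of `A·y = h`, `c = y/s`, reported
in µM for targets only. Negative solutions are flagged, not clipped (an
opt-in non-negative least-squares mode exists); further flags mark window-
edge picks, off-diagonal row mass above half the diagonal
(`high_interference`), and concentrations below 10× the baseline-noise-
equivalent concentration (`below_loq`, noise from a quiet 9.5–9.9 ppm
region).

## Background extraction

Evaluation needs backgrounds whose truth is exact, built from a realistic
spectrum in four steps per segment: (1) spike detection — local maxima whose
prominence over a 301-bin running median exceeds 4× a robust noise scale and
whose prominence is *sharp* (the trace falls by half of it within 10 bins on
each side; metabolite lines are 6–10 bins FWHM at canonical resolution);
candidates that never return to the reference within 60 bins on either side
are broad features, not spikes. The noise scale is the larger of a
first-difference MAD estimate and deviation-from-reference scales (MAD and
90th percentile), so the detector stays silent on already-smooth traces
whose bin-to-bin noise has collapsed. (2) Border walk outward until the
trace reaches the reference or the slope inverts for 3 bins, capped at 60
bins; overlapping regions merge. (3) Depletion by a least-squares line
through 3 flanking bins per side (one-sided constant extension at vector
ends). Detect → deplete iterates to a fixpoint (≤ 3 passes) because bridging
a partially caught multiplet can leave a narrow remnant. (4) Centred moving
average with mirror padding at window 51 / 201 / 801 bins, producing models
A, B, C of decreasing roughness (`Σ(Δ²z)²` measured per segment; differences
across the water gap are meaningless). The contract — no residual spikes in
A/B/C, roughness A ≥ B ≥ C — is asserted in the tests. These models are
evaluation floors, not physical lipid models.

## Synthetic study conditions

The generator emulates a root-exudate panel at 600 MHz: 24 target multiplets
(1–5 components, near-binomial intensity patterns with a slight roof
asymmetry so each multiplet has one unambiguous apex, ~1.2 Hz linewidths,
lognormal unit responses) spread over 0.8–9.0 ppm avoiding the solvent gap;
four unknown singlets at 0.931–0.972 ppm crowding a leucine-like doublet at
0.96 ppm; DSS at 0.29 mM. All component centres are snapped to the canonical
bin grid: real chemical shifts are arbitrary, but on-grid apexes make the
round-trip recovery identity machine-exact instead of carrying an
irreducible ~1% half-bin discretisation error that no height-based estimator
could distinguish from a true shift. Broad backgrounds are sums of eight
positive humps (FWHM 0.05–0.5 ppm) in 0.8–4.6 ppm plus a gentle tilt,
amplitude ~400 intensity units against multiplet unit responses of ~800 per
mM; measurement noise is Gaussian, σ = 4 for exudate analogues. Simulation
scaling levels span one decade geometrically (0.3–3, 7 levels), so the
narrow-to-broad ratio varies tenfold across the design. The spike-in design
assigns each of five metabolites its own five-level geometric series
(maxima 160–3200 µM, overall range 10–3200 µM, all above the limit of
quantification at σ = 0.5 noise), with a resident lactate-like doublet
interfering with the threonine-like reporter in the matrix arm only.

What the generator does *not* emulate: per-sample chemical-shift drift, pH
effects, non-Lorentzian shim distortions, t₁-noise ridges, or J-coupling
beyond fixed component patterns. Passing tests therefore demonstrate the
numerical correctness and robustness of the pipeline under its stated model,
not immunity to acquisition artefacts.

## Evaluation conventions

Ordinary least squares with `R² = 1 − SSres/SStot` (constant response ⇒
R² = 0 by convention); regressions with R² < 0.9900 are flagged. Accuracy
condensates: percent difference `100·|c_ref − c_test|/c_ref` and the
intercept as a percentage of the metabolite's maximum concentration. A
reporter counts as free of background interference when the background
intensity at its picked position is below 1% of its top-level true height;
under that cut the simulation study recovers slopes within 1%, intercepts
below 1% of the maximum height and R² ≈ 1, while background-affected
reporters degrade in proportion to how well the baseline tracks their local
background. Simulation and spike-in studies run at the problem sizes above
(21 and 2 × 5 spectra of 51 000 bins), which complete in seconds while
exercising every pipeline stage at full spectral resolution.

## Known limitations

- Quantification is height-based; systematic library linewidth errors map
  directly into concentration errors (no per-spectrum lineshape refit).
- Reporter picking takes the tallest bin in a fixed window: an unmodelled
  signal taller than the intended one inside the window is silently picked.
- The baseline stage biases heights by a few percent in crowded regions even
  without background (see above); where that matters, quantify with the
  baseline bypassed or model the offending neighbours as interferents.
- The λ map is manual by design; no automatic per-spectrum λ selection is
  attempted.
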