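"""Absolute quantification of a 24-metabolite panel from one spectrum.

Renders a noisy exudate analogue with known concentrations, runs the full
pipeline (baseline correction, internal-standard calibration, reporter
picking, interference-corrected linear solve) and compares the reported
concentrations in µM with the generating truth.
"""

import aquanmr as aq

axis = aq.canonical_axis()
library = aq.make_synthetic_library(seed=0, preset="paper_panel")
background = aq.make_broad_background(axis, seed=1)
spectrum, truth_mM = aq.make_exudate_spectrum(
    library, axis, background=background, noise_sigma=2.0, seed=3
)

results = aq.extended_aqua(spectrum, library, lam_map=aq.RegionLambdaMap(1e7))

print(f"{'metabolite':<14} {'true µM':>9} {'found µM':>9} {'err %':>7}  flags")
n_close = 0
for r in sorted(results, key=lambda r: r.metabolite):
    true_uM = truth_mM[r.metabolite] * 1000
    err = 100 * abs(r.concentration_uM - true_uM) / true_uM
    n_close += err < 10
    print(f"{r.metabolite:<14} {true_uM:9.1f} {r.concentration_uM:9.1f} "
          f"{err:7.1f}  {','.join(sorted(r.flags))}")
print(f"\n{n_close} of {len(results)} targets within 10% of truth; larger "
      "errors concentrate where the broad background overlaps a reporter.")
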