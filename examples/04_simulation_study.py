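"""Simulation study: 3 backgrounds x 7 scaling levels, corrected at λ = 1e7.

A known narrow-signal spectrum is added to three background models at seven
intensities (21 spectra); after baseline correction, each metabolite's
corrected reporter height is regressed on its true height.  Slopes and R²
near one with intercepts near zero mean the correction removed the
background without damaging the signals.
"""

from dataclasses import replace

import aquanmr as aq
from aquanmr.evaluation import background_interference_fraction

design, library = aq.default_simulation_design(seed=0)
report = aq.run_simulation_study(replace(design, lambdas=(1e7,)), library)

frac = background_interference_fraction(design, library)
merged = report.merge(frac, on=["metabolite", "background"])
clean = merged[merged.bg_fraction < 0.01]

print(f"all {len(report)} regressions   : slope "
      f"[{report.slope.min():.3f}, {report.slope.max():.3f}]  "
      f"min R² {report.r2.min():.4f}")
print(f"background-free reporters ({len(clean):2d}): slope "
      f"[{clean.slope.min():.3f}, {clean.slope.max():.3f}]  "
      f"min R² {clean.r2.min():.6f}  max |intercept| "
      f"{clean.rel_intercept.abs().max():.2f}% of max height")
print(f"regressions flagged R² < 0.99  : {int(report.r2_flag.sum())}")
print("Reporters outside background-affected regions recover essentially "
      "perfectly; accuracy elsewhere depends on how well the baseline "
      "model tracks the local background.")
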