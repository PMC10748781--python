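"""Synthetic spike-in: matrix arm with broad background vs clean blank arm.

Five metabolites are spiked over 10–3200 µM into a complex matrix (quantified
with baseline correction) and into blanks (quantified without it).  Per
metabolite, matrix concentrations are regressed on blank concentrations:
slope ≈ 1 and intercept ≈ 0 mean the baseline stage does not bias the
quantification.
"""

import aquanmr as aq

matrix, blanks, truth, library = aq.make_spikein_dataset(seed=0)
report = aq.run_spikein_study(matrix, blanks, truth, library)

print(f"{'metabolite':<14} {'max µM':>7} {'slope':>7} {'R²':>8} "
      f"{'rel.intercept %':>15} {'mean diff %':>11}")
for _, row in report.iterrows():
    print(f"{row.metabolite:<14} {row.max_conc_uM:7.0f} {row.slope:7.3f} "
          f"{row.r2:8.4f} {row.rel_intercept:15.3f} {row.mean_pct_diff:11.1f}")
print("\nSlopes within a few percent of one and R² > 0.999 show the two "
      "pipelines agree; percent differences are largest for the lowest "
      "spiked concentrations, where any residual baseline error weighs most.")
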