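"""Extract the three spectral-background models A/B/C from one spectrum.

The extractor localises narrow high-intensity signals, bridges them with
fitted lines, and smooths the result at three window lengths, producing
background models of decreasing roughness that serve as exact ground truth
in simulation studies.
"""

import numpy as np

import aquanmr as aq
from aquanmr.background import detect_spikes

axis = aq.canonical_axis()
library = aq.make_synthetic_library(seed=0, preset="paper_panel")
spectrum, _ = aq.make_exudate_spectrum(
    library, axis, background=aq.make_broad_background(axis, seed=1),
    noise_sigma=4.0, seed=2,
)

models = aq.make_backgrounds(spectrum)
for name, bg in zip("ABC", models):
    rough = sum(
        float(np.sum(np.diff(bg.intensities[sl], 2) ** 2))
        for sl in axis.segment_slices()
    )
    residual = sum(
        len(detect_spikes(bg.intensities[sl])) for sl in axis.segment_slices()
    )
    print(f"model {name}: roughness {rough:10.2f}   residual spikes {residual}")
print("Roughness must fall from A to C and no narrow signal may survive: "
      "the models are smooth floors, free of metabolite lines.")
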