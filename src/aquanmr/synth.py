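"""Synthetic study conditions: broad backgrounds, exudate analogues, spike-ins.

These generators emulate the structure of plant root-exudate ¹H NMR data:
a panel of ~24 small-molecule multiplets over 0.8–9 ppm at 600 MHz, a crowded
cluster of unknown singlets near 0.93–0.97 ppm, an internal standard (DSS,
0.29 mM) at 0 ppm, broad positive background humps concentrated in the
low-frequency half of the spectrum (unassigned macromolecules, plausibly
lipids), and white measurement noise.  Everything is deterministic in the
seed.

What the generator does *not* emulate: pH- and matrix-dependent chemical
shift drift between samples, J-coupling roof effects beyond a fixed pattern,
non-Lorentzian lineshape distortion from imperfect shimming, and t₁ noise
ridges.  Conclusions from synthetic runs therefore speak to the numerical
behaviour of the pipeline, not to acquisition artefacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .background import DEFAULT_LEVELS, make_backgrounds
from .evaluation import SimulationDesign
from .library import Library, make_synthetic_library, render_mixture
from .spectral import Axis, Spectrum, build_axis

__all__ = [
    "canonical_axis",
    "make_broad_background",
    "make_exudate_spectrum",
    "default_simulation_design",
    "make_spikein_dataset",
]

#: the canonical acquisition layout: two segments around the water gap
CANONICAL_REGIONS = [(-0.50, 4.68), (4.98, 10.00)]
CANONICAL_BIN_WIDTH = 0.0002


def canonical_axis(frequency_mhz: float = 600.0) -> Axis:
    """51 000-bin axis: −0.50–4.68 and 4.98–10.00 ppm at 0.0002 ppm/bin."""
    return build_axis(CANONICAL_REGIONS, CANONICAL_BIN_WIDTH, frequency_mhz)


def make_broad_background(
    axis: Axis,
    seed: int = 0,
    amplitude: float = 400.0,
    n_humps: int = 8,
) -> Spectrum:
    """Smooth positive background of broad humps in the 0.8–4.6 ppm region.

    Hump widths span 0.05–0.5 ppm (25–250 Hz at 600 MHz), far wider than the
    ~1.2 Hz metabolite lines, mimicking the macromolecular signal floor.
    ``amplitude`` sets the typical hump apex in library intensity units.
    """
    rng = np.random.default_rng(seed)
    centers = axis.centers()
    out = np.zeros_like(centers)
    for _ in range(n_humps):
        pos = rng.uniform(0.8, 4.6)
        width = rng.uniform(0.05, 0.5)
        height = amplitude * rng.uniform(0.3, 1.0)
        gamma = width / 2.0
        out += height * gamma**2 / ((centers - pos) ** 2 + gamma**2)
    # gentle global tilt such as a residual first-order baseline error
    out += 0.05 * amplitude * (centers.max() - centers) / (centers.max() - centers.min())
    return Spectrum(axis, out, label=f"broad background (seed {seed})")


def make_exudate_spectrum(
    library: Library,
    axis: Axis,
    concentrations_mM: dict[str, float] | None = None,
    background: Spectrum | None = None,
    noise_sigma: float = 4.0,
    seed: int = 0,
    dss: bool = True,
) -> tuple[Spectrum, dict[str, float]]:
    """Root-exudate analogue: mixture + broad background + white noise.

    When no concentration map is given, targets draw log-uniform from
    0.2–2 mM and interferents from 0.2–1 mM (the mM-scale range typical of
    concentrated exudate samples).  Returns the spectrum and the ground-truth
    concentration map (internal standard included when ``dss``).
    """
    rng = np.random.default_rng(seed)
    if concentrations_mM is None:
        concentrations_mM = {}
        for e in library.targets:
            concentrations_mM[e.name] = float(np.exp(rng.uniform(np.log(0.2), np.log(2.0))))
        for e in library.interferents:
            concentrations_mM[e.name] = float(np.exp(rng.uniform(np.log(0.2), np.log(1.0))))
    truth = dict(concentrations_mM)
    if dss:
        truth[library.internal_standard.name] = library.known_concentration_mM
    spec = render_mixture(library, axis, truth)
    vals = spec.intensities
    if background is not None:
        if background.axis != axis:
            raise ValueError("background axis mismatch")
        vals = vals + background.intensities
    if noise_sigma > 0:
        vals = vals + rng.normal(0.0, noise_sigma, size=len(vals))
    return (
        Spectrum(axis, vals, label=f"synthetic exudate (seed {seed})"),
        truth,
    )


def default_simulation_design(
    seed: int = 0,
    library: Library | None = None,
    lambdas: tuple[float, ...] = (1e6, 1e7, 1e8),
    n_levels: int = 7,
) -> tuple[SimulationDesign, Library]:
    """Canonical 3 × 7 simulation design built entirely from synthetic parts.

    One synthetic exudate spectrum is reduced to three background models
    (A/B/C) by the spike-depletion/smoothing extractor; the narrow spectrum
    is the noiseless rendered panel at 1 mM per metabolite ("normalised"
    reference intensities summed); scaling levels span one decade
    geometrically (0.3–3), so the narrow:broad ratio varies tenfold across
    the design.
    """
    axis = canonical_axis()
    if library is None:
        library = make_synthetic_library(seed=seed, preset="paper_panel")
    background = make_broad_background(axis, seed=seed + 1)
    source, _ = make_exudate_spectrum(
        library, axis, background=background, noise_sigma=4.0, seed=seed + 2
    )
    bgs = make_backgrounds(source, DEFAULT_LEVELS)
    narrow = render_mixture(
        library,
        axis,
        {e.name: 1.0 for e in (*library.targets, *library.interferents)}
        | {library.internal_standard.name: library.known_concentration_mM},
    )
    levels = tuple(float(v) for v in np.geomspace(0.3, 3.0, n_levels))
    design = SimulationDesign(
        backgrounds=tuple(bgs),
        narrow_spectrum=narrow,
        scaling_levels=levels,
        lambdas=lambdas,
    )
    return design, library


# -- spike-in dataset --------------------------------------------------------

#: per-metabolite maximum spiked concentration, µM (one decade-plus spread,
#: overall design range 10–3200 µM)
_SPIKE_MAX_UM = {
    "asparagine": 1600.0,
    "gaba": 400.0,
    "tartaric_acid": 800.0,
    "threonine": 160.0,
    "xylose": 3200.0,
}
_N_SPIKE_LEVELS = 5


def make_spikein_dataset(
    seed: int = 0,
    noise_sigma: float = 0.5,
    background_amplitude: float = 300.0,
) -> tuple[list[Spectrum], list[Spectrum], pd.DataFrame, Library]:
    """Paired spiked-matrix / spiked-blank synthetic spectra plus truth table.

    Five spiked metabolites (named for the compound class they stand in for;
    all signals are synthetic) span 10–3200 µM over five geometric levels,
    each metabolite with its own maximum.  The matrix arm adds a broad
    background and a resident lactate-like metabolite at 1 mM whose doublet
    neighbours the threonine-like reporter; the blank arm has neither.  Both
    arms carry DSS and seed-fixed white noise.

    Returns (matrix_spectra, blank_spectra, truth_table_uM, library).
    """
    rng = np.random.default_rng(seed)
    axis = canonical_axis()
    lib = _spikein_library(seed)
    background = make_broad_background(axis, seed=seed + 10,
                                       amplitude=background_amplitude)

    levels = {
        name: np.geomspace(maxc / 16.0, maxc, _N_SPIKE_LEVELS)
        for name, maxc in _SPIKE_MAX_UM.items()
    }
    truth_rows = [
        {name: float(levels[name][i]) for name in _SPIKE_MAX_UM}
        for i in range(_N_SPIKE_LEVELS)
    ]
    truth = pd.DataFrame(truth_rows)

    matrix_spectra, blank_spectra = [], []
    for i, row in enumerate(truth_rows):
        conc = {name: uM / 1000.0 for name, uM in row.items()}
        conc[lib.internal_standard.name] = lib.known_concentration_mM
        base = render_mixture(lib, axis, conc | {"lactic_acid": 0.0})

        blank_vals = base.intensities + rng.normal(0, noise_sigma, axis.n_bins)
        blank_spectra.append(
            Spectrum(axis, blank_vals, label=f"blank_{i}")
        )

        matrix_conc = dict(conc)
        matrix_conc["lactic_acid"] = 1.0
        matrix_vals = (
            render_mixture(lib, axis, matrix_conc).intensities
            + background.intensities
            + rng.normal(0, noise_sigma, axis.n_bins)
        )
        matrix_spectra.append(
            Spectrum(axis, matrix_vals, label=f"matrix_{i}")
        )
    return matrix_spectra, blank_spectra, truth, lib


def _spikein_library(seed: int) -> Library:
    """Six-entry panel for the spike-in study: five spiked metabolites plus a
    resident lactate-like doublet that interferes with the threonine window."""
    from .library import _make_entry, make_dss_entry  # shared constructors

    freq = 600.0
    entries = (
        _make_entry("asparagine", "target", 2.95, 2, 700.0, 7.0, 1.2, 0.012, freq),
        _make_entry("gaba", "target", 3.01, 5, 500.0, 7.5, 1.2, 0.012, freq),
        _make_entry("tartaric_acid", "target", 4.34, 1, 900.0, 7.0, 1.2, 0.012, freq),
        _make_entry("threonine", "target", 1.32, 2, 800.0, 6.5, 1.2, 0.010, freq),
        _make_entry("xylose", "target", 5.20, 2, 600.0, 7.0, 1.2, 0.012, freq),
        _make_entry("lactic_acid", "target", 1.36, 2, 850.0, 7.0, 1.2, 0.010, freq),
    )
    return Library(
        entries=entries,
        frequency_mhz=freq,
        internal_standard=make_dss_entry(freq),
        known_concentration_mM=0.29,
    )
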