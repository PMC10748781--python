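"""Metabolite signal models: sums of Lorentzians, reporter windows, library I/O.

Every metabolite is modelled as a sum of Lorentzian components
``height · γ² / ((δ − δ₀)² + γ²)`` with the half width γ stored as a FWHM in
Hz (linewidths transfer across field strengths; ppm widths would not).  One
*reporter* signal per metabolite — a ppm window around the tallest useful
multiplet — drives quantification: the library records the model intensity at
the reporter apex for a 1 mM solution (``unit_response``), which ties library
intensity units to absolute concentration once the spectrum scale has been
calibrated against the internal standard.

Entries carry a role: ``target`` metabolites are quantified and reported;
``interferent`` entries are unknown signals (modelled as single Lorentzians)
that overlap a target's reporter and are solved for only so that their
contribution can be subtracted, never reported.

J-coupling fine structure is encoded as explicit component lists (a 1:2:1
triplet is three components); no spin simulation is attempted, which is
sufficient for height-based quantification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .spectral import Axis, Spectrum

__all__ = [
    "LorentzianComponent",
    "MetaboliteEntry",
    "Library",
    "entry_profile",
    "render_entry",
    "render_mixture",
    "load_library",
    "save_library",
    "make_synthetic_library",
    "compute_unit_response",
]

#: canonical bin grid used by the synthetic generator to snap signal centres
GRID_ORIGIN_PPM = -0.5
GRID_WIDTH_PPM = 0.0002

#: tolerance for the unit_response self-consistency check on load
_UNIT_RESPONSE_RTOL = 1e-3


@dataclass(frozen=True)
class LorentzianComponent:
    center_ppm: float
    rel_height: float
    fwhm_hz: float

    def __post_init__(self) -> None:
        if self.rel_height <= 0:
            raise ValueError("component rel_height must be positive")
        if self.fwhm_hz <= 0:
            raise ValueError("component fwhm_hz must be positive")


@dataclass(frozen=True)
class MetaboliteEntry:
    name: str
    role: str  # "target" | "interferent"
    components: tuple[LorentzianComponent, ...]
    reporter_center_ppm: float
    window_halfwidth_ppm: float
    unit_response: float

    def __post_init__(self) -> None:
        if self.role not in ("target", "interferent"):
            raise ValueError(f"{self.name}: role must be 'target' or 'interferent'")
        if not self.components:
            raise ValueError(f"{self.name}: needs at least one component")
        if self.window_halfwidth_ppm <= 0:
            raise ValueError(f"{self.name}: window_halfwidth_ppm must be positive")
        if self.unit_response <= 0:
            raise ValueError(f"{self.name}: unit_response must be positive")
        lo = min(c.center_ppm for c in self.components) - self.window_halfwidth_ppm
        hi = max(c.center_ppm for c in self.components) + self.window_halfwidth_ppm
        if not (lo <= self.reporter_center_ppm <= hi):
            raise ValueError(f"{self.name}: reporter centre lies outside the component span")

    @property
    def window(self) -> tuple[float, float]:
        return (
            self.reporter_center_ppm - self.window_halfwidth_ppm,
            self.reporter_center_ppm + self.window_halfwidth_ppm,
        )


@dataclass(frozen=True)
class Library:
    """A metabolite panel plus the internal standard (DSS) and its known
    concentration in mM."""

    entries: tuple[MetaboliteEntry, ...]
    frequency_mhz: float
    internal_standard: MetaboliteEntry
    known_concentration_mM: float = 0.29

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("library entry names must be unique")
        if self.internal_standard.name in names:
            raise ValueError("internal standard must not duplicate a panel entry")
        if self.known_concentration_mM <= 0:
            raise ValueError("known_concentration_mM must be positive")
        if self.frequency_mhz <= 0:
            raise ValueError("frequency_mhz must be positive")

    @property
    def targets(self) -> tuple[MetaboliteEntry, ...]:
        return tuple(e for e in self.entries if e.role == "target")

    @property
    def interferents(self) -> tuple[MetaboliteEntry, ...]:
        return tuple(e for e in self.entries if e.role == "interferent")

    def entry(self, name: str) -> MetaboliteEntry:
        if name == self.internal_standard.name:
            return self.internal_standard
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


# -- rendering ---------------------------------------------------------------


def entry_profile(
    entry: MetaboliteEntry,
    ppm: np.ndarray,
    frequency_mhz: float,
    concentration_mM: float = 1.0,
    shift_offset_ppm: float = 0.0,
    fwhm_scale: float = 1.0,
) -> np.ndarray:
    """Closed-form model intensity of an entry at arbitrary ppm positions.

    γ (half width at half maximum, in ppm) is ``fwhm_hz·fwhm_scale / MHz / 2``.
    """
    if concentration_mM < 0:
        raise ValueError("concentration must be non-negative")
    if fwhm_scale <= 0:
        raise ValueError("fwhm_scale must be positive")
    ppm = np.asarray(ppm, dtype=float)
    out = np.zeros_like(ppm)
    for comp in entry.components:
        gamma = comp.fwhm_hz * fwhm_scale / frequency_mhz / 2.0
        delta = ppm - comp.center_ppm - shift_offset_ppm
        out += comp.rel_height * gamma**2 / (delta**2 + gamma**2)
    return concentration_mM * out


def render_entry(
    entry: MetaboliteEntry,
    axis: Axis,
    concentration_mM: float,
    shift_offset_ppm: float = 0.0,
    fwhm_scale: float = 1.0,
) -> Spectrum:
    """Render one entry onto an axis; the apex of an isolated component equals
    ``concentration × rel_height``."""
    centers = axis.centers()
    lo, hi = centers[0], centers[-1]
    if all(
        not (lo <= c.center_ppm + shift_offset_ppm <= hi) for c in entry.components
    ):
        warnings.warn(f"{entry.name}: all components fall outside the axis")
        return Spectrum(axis, np.zeros(axis.n_bins), label=entry.name)
    vals = entry_profile(
        entry, centers, axis.frequency_mhz, concentration_mM, shift_offset_ppm, fwhm_scale
    )
    return Spectrum(axis, vals, label=entry.name)


def render_mixture(
    library: Library,
    axis: Axis,
    concentrations_mM: dict[str, float],
    offsets_ppm: dict[str, float] | None = None,
) -> Spectrum:
    """Sum of rendered entries; names missing from the map default to 0 mM."""
    offsets_ppm = offsets_ppm or {}
    known = {e.name for e in library.entries} | {library.internal_standard.name}
    for name in list(concentrations_mM) + list(offsets_ppm):
        if name not in known:
            raise ValueError(f"unknown library entry: {name!r}")
    total = np.zeros(axis.n_bins)
    for name, conc in concentrations_mM.items():
        if conc == 0:
            continue
        entry = library.entry(name)
        total += entry_profile(
            entry,
            axis.centers(),
            axis.frequency_mhz,
            conc,
            offsets_ppm.get(name, 0.0),
        )
    return Spectrum(axis, total, label="mixture")


def compute_unit_response(
    entry_components: tuple[LorentzianComponent, ...],
    window: tuple[float, float],
    frequency_mhz: float,
    oversample: int = 25,
) -> float:
    """Apex model intensity at 1 mM inside the reporter window, evaluated on a
    grid ``oversample`` times finer than the narrowest linewidth."""
    step = min(c.fwhm_hz for c in entry_components) / frequency_mhz / oversample
    grid = np.arange(window[0], window[1] + step, step)
    out = np.zeros_like(grid)
    for comp in entry_components:
        gamma = comp.fwhm_hz / frequency_mhz / 2.0
        out += comp.rel_height * gamma**2 / ((grid - comp.center_ppm) ** 2 + gamma**2)
    return float(out.max())


# -- JSON I/O ----------------------------------------------------------------


def _entry_to_dict(entry: MetaboliteEntry) -> dict:
    return {
        "name": entry.name,
        "role": entry.role,
        "reporter_center_ppm": entry.reporter_center_ppm,
        "window_halfwidth_ppm": entry.window_halfwidth_ppm,
        "unit_response": entry.unit_response,
        "components": [asdict(c) for c in entry.components],
    }


def _entry_from_dict(d: dict, path: str) -> MetaboliteEntry:
    try:
        comps = tuple(
            LorentzianComponent(c["center_ppm"], c["rel_height"], c["fwhm_hz"])
            for c in d["components"]
        )
        return MetaboliteEntry(
            name=d["name"],
            role=d["role"],
            components=comps,
            reporter_center_ppm=d["reporter_center_ppm"],
            window_halfwidth_ppm=d["window_halfwidth_ppm"],
            unit_response=d["unit_response"],
        )
    except KeyError as exc:
        raise ValueError(f"library schema violation at {path}: missing field {exc}") from exc


def save_library(library: Library, path: str | Path) -> None:
    doc = {
        "frequency_mhz": library.frequency_mhz,
        "internal_standard": {
            **_entry_to_dict(library.internal_standard),
            "known_concentration_mM": library.known_concentration_mM,
        },
        "entries": [_entry_to_dict(e) for e in library.entries],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_library(path: str | Path) -> Library:
    """Load a library JSON file, re-validating unit_response self-consistency."""
    doc = json.loads(Path(path).read_text())
    if "internal_standard" not in doc:
        raise ValueError(f"{path}: missing internal_standard")
    freq = doc.get("frequency_mhz")
    if freq is None:
        raise ValueError(f"{path}: missing frequency_mhz")
    entries = tuple(
        _entry_from_dict(d, f"entries[{i}]") for i, d in enumerate(doc.get("entries", []))
    )
    is_doc = doc["internal_standard"]
    standard = _entry_from_dict(is_doc, "internal_standard")
    lib = Library(
        entries=entries,
        frequency_mhz=freq,
        internal_standard=standard,
        known_concentration_mM=is_doc.get("known_concentration_mM", 0.29),
    )
    for e in (*lib.entries, lib.internal_standard):
        expected = compute_unit_response(e.components, e.window, freq)
        if abs(e.unit_response - expected) > _UNIT_RESPONSE_RTOL * expected:
            raise ValueError(
                f"{path}: entry {e.name!r}: unit_response {e.unit_response} "
                f"inconsistent with components (expected {expected:.6g})"
            )
    return lib


# -- synthetic library generation --------------------------------------------


def _snap_to_grid(ppm: float) -> float:
    """Nearest canonical bin centre (centres at origin + (i + 0.5)·width)."""
    i = round((ppm - GRID_ORIGIN_PPM) / GRID_WIDTH_PPM - 0.5)
    return GRID_ORIGIN_PPM + (i + 0.5) * GRID_WIDTH_PPM


# near-binomial multiplet intensity patterns (singlet ... quintet) with a
# slight roof asymmetry so every multiplet has one unambiguous apex
_MULTIPLET_PATTERNS = {
    1: (1.0,),
    2: (1.0, 0.93),
    3: (0.5, 1.0, 0.46),
    4: (0.34, 1.0, 0.93, 0.31),
    5: (0.17, 0.67, 1.0, 0.62, 0.15),
}


def _make_entry(
    name: str,
    role: str,
    center: float,
    n_comp: int,
    base_height: float,
    j_hz: float,
    fwhm_hz: float,
    window_halfwidth: float,
    frequency_mhz: float,
) -> MetaboliteEntry:
    pattern = _MULTIPLET_PATTERNS[n_comp]
    spacing = j_hz / frequency_mhz
    comps = []
    for k, h in enumerate(pattern):
        pos = _snap_to_grid(center + (k - (n_comp - 1) / 2) * spacing)
        comps.append(LorentzianComponent(pos, base_height * h, fwhm_hz))
    reporter = max(comps, key=lambda c: c.rel_height).center_ppm
    window = (reporter - window_halfwidth, reporter + window_halfwidth)
    ur = compute_unit_response(tuple(comps), window, frequency_mhz)
    return MetaboliteEntry(
        name=name,
        role=role,
        components=tuple(comps),
        reporter_center_ppm=reporter,
        window_halfwidth_ppm=window_halfwidth,
        unit_response=ur,
    )


def make_dss_entry(frequency_mhz: float = 600.0, rel_height: float = 2500.0) -> MetaboliteEntry:
    """Internal-standard singlet at 0.00 ppm (snapped to the canonical grid)."""
    center = _snap_to_grid(0.0)
    comp = LorentzianComponent(center, rel_height, 1.2)
    window = (center - 0.02, center + 0.02)
    ur = compute_unit_response((comp,), window, frequency_mhz)
    return MetaboliteEntry(
        name="DSS",
        role="target",
        components=(comp,),
        reporter_center_ppm=center,
        window_halfwidth_ppm=0.02,
        unit_response=ur,
    )


def make_synthetic_library(
    n_targets: int = 24,
    n_interferents: int = 4,
    seed: int = 0,
    overlap_level: str = "medium",
    frequency_mhz: float = 600.0,
    preset: str | None = None,
) -> Library:
    """Deterministic synthetic metabolite panel emulating a root-exudate study.

    Targets are 1–5-component multiplets spread over 0.8–9.0 ppm (avoiding the
    4.68–4.98 ppm solvent gap) with ~1.2 Hz linewidths; ``overlap_level``
    controls how tightly reporter windows may approach each other (``low``
    guarantees disjoint windows).  The ``paper_panel`` preset emits 24 targets
    plus 4 interferent singlets between 0.93 and 0.97 ppm crowding a
    leucine-like doublet at 0.96 ppm.  All component centres are snapped to
    the canonical 0.0002 ppm bin grid.
    """
    if preset == "paper_panel":
        n_targets, n_interferents, overlap_level = 24, 4, "medium"
    elif preset is not None:
        raise ValueError(f"unknown preset {preset!r}")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if overlap_level not in ("low", "medium", "high"):
        raise ValueError("overlap_level must be low|medium|high")

    rng = np.random.default_rng(seed)
    halfwidth = 0.012
    min_sep = {"low": 2.5 * halfwidth, "medium": 0.06, "high": 0.02}[overlap_level]
    # note: "low" forces disjoint windows; medium/high govern centre spacing only

    entries: list[MetaboliteEntry] = []
    centers: list[float] = []

    def _place(lo: float, hi: float, sep: float) -> float:
        for _ in range(4000):
            c = rng.uniform(lo, hi)
            if 4.62 <= c <= 5.04:  # stay clear of the solvent gap
                continue
            if all(abs(c - o) >= sep for o in centers):
                return c
        raise RuntimeError("could not place a signal; panel too dense")

    n_made = 0
    if preset == "paper_panel":
        # narrow window: the crowded 0.93-0.97 ppm cluster sits just outside
        leu = _make_entry(
            "leucine_like", "target", 0.960, 2, 900.0, 6.5, 1.2, 0.004, frequency_mhz
        )
        entries.append(leu)
        centers.append(0.960)
        n_made = 1

    sep = max(min_sep, 2.5 * halfwidth) if overlap_level == "low" else min_sep
    for i in range(n_made, n_targets):
        c = _place(0.8, 9.0, sep)
        centers.append(c)
        n_comp = int(rng.integers(1, 6))
        height = float(rng.lognormal(mean=np.log(800.0), sigma=0.5))
        j = float(rng.uniform(6.0, 8.0))
        fw = float(rng.normal(1.2, 0.05))
        entries.append(
            _make_entry(
                f"target_{i:02d}", "target", c, n_comp, height, j, max(fw, 0.8),
                halfwidth, frequency_mhz,
            )
        )

    if preset == "paper_panel":
        # unknown singlets crowding the leucine-like doublet (0.9546/0.9654);
        # the upfield three sit inside 0.93-0.95, the fourth just downfield of
        # the doublet with enough clearance that a small uniform shift cannot
        # push the leucine line into its picking window
        interferent_pos = [0.9310, 0.9400, 0.9480, 0.9720]
    else:
        interferent_pos = [
            _place(0.9, 1.0, 0.008) for _ in range(n_interferents)
        ]
    for k, pos in enumerate(interferent_pos[:n_interferents]):
        height = float(rng.lognormal(mean=np.log(600.0), sigma=0.3))
        entries.append(
            _make_entry(
                f"unknown_{k}", "interferent", pos, 1, height, 7.0, 1.2,
                0.003, frequency_mhz,
            )
        )

    return Library(
        entries=tuple(entries),
        frequency_mhz=frequency_mhz,
        internal_standard=make_dss_entry(frequency_mhz),
        known_concentration_mM=0.29,
    )
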