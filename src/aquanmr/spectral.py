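"""Spectrum data model, binning, FWHM quality control and plain-text I/O.

A :class:`Spectrum` is a uniformly binned 1D ¹H NMR trace defined on an
:class:`Axis` made of one or more disjoint ppm segments.  Segments exist so
that the solvent (water) region can be a *true gap* in the axis rather than a
run of zero-filled bins: downstream baseline correction must never bridge the
suppressed solvent signal.  Intensities are stored in ascending-ppm order; NMR
convention displays spectra with ppm decreasing to the right, which is a
presentation concern only.

Bins are half-open intervals ``[start + i*w, start + (i+1)*w)`` with the bin
centre at ``start + (i + 0.5)*w``.  The chemical-shift / frequency conversion
used throughout is ``Hz = ppm * spectrometer_frequency_MHz``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Axis",
    "Spectrum",
    "QcResult",
    "build_axis",
    "bin_raw",
    "measure_fwhm",
    "read_spectrum",
    "write_spectrum",
    "read_table",
    "write_table",
]

#: relative tolerance for "(end - start) / width is an integer" checks
_INTEGRALITY_RTOL = 1e-9


@dataclass(frozen=True)
class Axis:
    """Segmented, uniformly binned chemical-shift axis.

    Parameters
    ----------
    segments
        Ordered tuple of ``(start_ppm, end_ppm, bin_width_ppm)`` triples,
        non-overlapping and sorted ascending.
    frequency_mhz
        Spectrometer ¹H frequency in MHz (600 for the instrument class this
        package was written around).
    """

    segments: tuple[tuple[float, float, float], ...]
    frequency_mhz: float = 600.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("axis needs at least one segment")
        if self.frequency_mhz <= 0:
            raise ValueError("frequency_mhz must be positive")
        prev_end = -math.inf
        for seg in self.segments:
            start, end, width = seg
            if not (start < end):
                raise ValueError(f"segment {seg}: start must be < end")
            if width <= 0:
                raise ValueError(f"segment {seg}: bin width must be positive")
            ratio = (end - start) / width
            if abs(ratio - round(ratio)) > _INTEGRALITY_RTOL * max(1.0, ratio):
                raise ValueError(
                    f"segment ({start}, {end}): length is not an integral "
                    f"multiple of bin width {width}"
                )
            if start < prev_end:
                raise ValueError(f"segment {seg} overlaps the previous one")
            prev_end = end

    # -- geometry ----------------------------------------------------------

    def segment_n_bins(self, i: int) -> int:
        start, end, width = self.segments[i]
        return int(round((end - start) / width))

    @property
    def n_bins(self) -> int:
        return sum(self.segment_n_bins(i) for i in range(len(self.segments)))

    def segment_slices(self) -> list[slice]:
        """Index slice of each segment within the flat intensity vector."""
        out, off = [], 0
        for i in range(len(self.segments)):
            n = self.segment_n_bins(i)
            out.append(slice(off, off + n))
            off += n
        return out

    def centers(self) -> np.ndarray:
        """Bin-centre ppm values for all segments, ascending."""
        parts = []
        for i, (start, _end, width) in enumerate(self.segments):
            n = self.segment_n_bins(i)
            parts.append(start + (np.arange(n) + 0.5) * width)
        return np.concatenate(parts)

    def locate(self, ppm: float) -> int:
        """Flat bin index containing ``ppm`` (half-open bins)."""
        off = 0
        for i, (start, end, width) in enumerate(self.segments):
            n = self.segment_n_bins(i)
            if start <= ppm < end:
                return off + min(int((ppm - start) / width), n - 1)
            off += n
        raise ValueError(f"{ppm} ppm lies outside the axis")

    def segment_of(self, ppm: float) -> int:
        for i, (start, end, _w) in enumerate(self.segments):
            if start <= ppm < end:
                return i
        raise ValueError(f"{ppm} ppm lies outside the axis")

    def window_bins(self, lo_ppm: float, hi_ppm: float) -> np.ndarray:
        """Flat indices of bins whose centres fall inside ``[lo, hi]``."""
        if not (lo_ppm < hi_ppm):
            raise ValueError("window must have lo < hi")
        centers = self.centers()
        idx = np.nonzero((centers >= lo_ppm) & (centers <= hi_ppm))[0]
        return idx


@dataclass
class Spectrum:
    """Binned spectrum: one intensity per axis bin, ascending ppm order."""

    axis: Axis
    intensities: np.ndarray
    label: str = ""
    scale_note: str = "raw"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or len(self.intensities) != self.axis.n_bins:
            raise ValueError(
                f"intensity vector has {len(self.intensities)} values, "
                f"axis has {self.axis.n_bins} bins"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must all be finite")

    def with_intensities(self, values: np.ndarray, scale_note: str | None = None) -> "Spectrum":
        return Spectrum(
            self.axis,
            values,
            label=self.label,
            scale_note=self.scale_note if scale_note is None else scale_note,
        )


@dataclass(frozen=True)
class QcResult:
    """Outcome of the DSS linewidth quality check."""

    fwhm_hz: float
    passed: bool
    threshold_hz: float = 1.20


def build_axis(
    regions: list[tuple[float, float]],
    bin_width_ppm: float,
    frequency_mhz: float = 600.0,
) -> Axis:
    """Construct a segmented axis from ppm intervals and a common bin width.

    Each interval length must be an integral multiple of the bin width; the
    canonical acquisition layout (−0.50–4.68 and 4.98–10.00 ppm at
    0.0002 ppm/bin) yields 25 900 + 25 100 = 51 000 bins, with the
    4.68–4.98 ppm water region left as a gap.
    """
    if bin_width_ppm <= 0:
        raise ValueError("bin width must be positive")
    segs = []
    for start, end in sorted(regions):
        ratio = (end - start) / bin_width_ppm
        if abs(ratio - round(ratio)) > _INTEGRALITY_RTOL * max(1.0, abs(ratio)):
            raise ValueError(
                f"interval ({start}, {end}) is not an integral number of "
                f"{bin_width_ppm} ppm bins"
            )
        segs.append((float(start), float(end), float(bin_width_ppm)))
    return Axis(tuple(segs), frequency_mhz=frequency_mhz)


def bin_raw(points: np.ndarray, axis: Axis) -> Spectrum:
    """Bin raw (ppm, intensity) points onto an axis by per-bin averaging.

    Each bin receives the mean of the raw intensities whose ppm falls inside
    its half-open interval; a point sitting exactly on a bin's right edge
    belongs to the next bin.  Bins that receive no points are zero and their
    count is logged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (ppm, intensity)")
    order = np.argsort(pts[:, 0], kind="stable")
    ppm, val = pts[order, 0], pts[order, 1]

    total = np.zeros(axis.n_bins)
    count = np.zeros(axis.n_bins, dtype=int)
    off = 0
    any_inside = False
    for i, (start, end, width) in enumerate(axis.segments):
        n = axis.segment_n_bins(i)
        inside = (ppm >= start) & (ppm < end)
        if inside.any():
            any_inside = True
            idx = np.minimum(((ppm[inside] - start) / width).astype(int), n - 1)
            np.add.at(total, off + idx, val[inside])
            np.add.at(count, off + idx, 1)
        off += n
    if not any_inside:
        raise ValueError("no points fall inside any axis segment")

    filled = count > 0
    out = np.zeros(axis.n_bins)
    out[filled] = total[filled] / count[filled]
    n_empty = int(np.sum(~filled))
    if n_empty:
        logger.warning("bin_raw: %d of %d bins received no points", n_empty, axis.n_bins)
    return Spectrum(axis, out)


def measure_fwhm(
    spectrum: Spectrum,
    window: tuple[float, float],
    threshold_hz: float = 1.20,
) -> QcResult:
    """Measure the full width at half maximum of the tallest signal in a window.

    The apex is the maximal bin inside the window; the two half-height
    crossings are found by linear interpolation between adjacent bin centres
    and the ppm width is converted to Hz with the axis frequency.  The check
    passes when the width does not exceed ``threshold_hz`` (spectra wider than
    1.20 Hz at the internal standard are re-acquired in practice).
    """
    lo, hi = window
    seg = spectrum.axis.segment_of(lo)
    if spectrum.axis.segment_of(hi - 1e-12) != seg:
        raise ValueError("FWHM window must lie inside a single axis segment")
    idx = spectrum.axis.window_bins(lo, hi)
    if len(idx) < 3:
        raise ValueError("FWHM window covers fewer than 3 bins")
    centers = spectrum.axis.centers()[idx]
    vals = spectrum.intensities[idx]
    apex = int(np.argmax(vals))
    half = vals[apex] / 2.0

    def _crossing(direction: int, side: str) -> float:
        i = apex
        while True:
            j = i + direction
            if j < 0 or j >= len(vals):
                raise ValueError(f"half height not crossed on the {side} side of the window")
            if vals[j] < half:
                # linear interpolation between centres j and i
                frac = (half - vals[j]) / (vals[i] - vals[j])
                return centers[j] + frac * (centers[i] - centers[j])
            i = j

    left = _crossing(-1, "left")
    right = _crossing(+1, "right")
    fwhm_ppm = right - left
    fwhm_hz = fwhm_ppm * spectrum.axis.frequency_mhz
    if fwhm_hz <= 0:
        raise ValueError("degenerate FWHM measurement")
    return QcResult(fwhm_hz=fwhm_hz, passed=fwhm_hz <= threshold_hz, threshold_hz=threshold_hz)


# -- file I/O --------------------------------------------------------------
#
# Spectrum file: two-column delimited text (ppm, intensity), '#' comments,
# with a JSON sidecar "<file>.json" carrying the axis metadata.  Intensities
# are written with repr-precision so a write→read round trip is bit exact.


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    centers = spectrum.axis.centers()
    with open(path, "w") as fh:
        fh.write(f"# aquanmr spectrum: {spectrum.label}\n")
        fh.write("# columns: ppm, intensity\n")
        for p, v in zip(centers, spectrum.intensities):
            fh.write(f"{p:.17g}\t{v:.17g}\n")
    meta = {
        "segments": [list(seg) for seg in spectrum.axis.segments],
        "frequency_mhz": spectrum.axis.frequency_mhz,
        "label": spectrum.label,
        "scale_note": spectrum.scale_note,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def _parse_two_columns(path: Path) -> tuple[np.ndarray, np.ndarray]:
    ppm, val = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.replace(",", "\t").split()
            if len(cells) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(cells)}")
            try:
                ppm.append(float(cells[0]))
                val.append(float(cells[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric cell") from exc
    if not ppm:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(ppm), np.asarray(val)


def _infer_axis(ppm: np.ndarray, frequency_mhz: float = 600.0) -> Axis:
    """Reconstruct a segmented axis from bin-centre ppm values (gap detection)."""
    diffs = np.diff(ppm)
    if np.any(diffs <= 0):
        raise ValueError("ppm column must be strictly ascending to infer an axis")
    width = float(np.median(diffs))
    breaks = np.nonzero(diffs > 1.5 * width)[0]
    bounds = [0, *(b + 1 for b in breaks), len(ppm)]
    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        segs.append((float(ppm[a] - width / 2), float(ppm[b - 1] + width / 2), width))
    return Axis(tuple(segs), frequency_mhz=frequency_mhz)


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column spectrum file; uses the JSON sidecar when present."""
    path = Path(path)
    ppm, val = _parse_two_columns(path)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        axis = Axis(
            tuple(tuple(seg) for seg in meta["segments"]),
            frequency_mhz=meta.get("frequency_mhz", 600.0),
        )
        if axis.n_bins != len(ppm):
            raise ValueError(
                f"{path}: {len(ppm)} data rows but sidecar axis has {axis.n_bins} bins"
            )
        if not np.allclose(axis.centers(), ppm, rtol=0, atol=1e-9):
            raise ValueError(f"{path}: ppm column disagrees with sidecar axis metadata")
        return Spectrum(axis, val, label=meta.get("label", path.stem),
                        scale_note=meta.get("scale_note", "raw"))
    axis = _infer_axis(ppm)
    return Spectrum(axis, val, label=path.stem)


def write_table(spectra: list[Spectrum], path: str | Path) -> None:
    """Write several spectra sharing one axis as a wide delimited matrix."""
    import pandas as pd

    if not spectra:
        raise ValueError("no spectra to write")
    axis = spectra[0].axis
    for s in spectra[1:]:
        if s.axis != axis:
            raise ValueError("all spectra in a table must share one axis")
    data = {"ppm": axis.centers()}
    for i, s in enumerate(spectra):
        data[s.label or f"spectrum_{i}"] = s.intensities
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path, axis: Axis | None = None) -> list[Spectrum]:
    """Read a wide multi-spectrum table (first column ppm, one column each)."""
    import pandas as pd

    frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    ppm = frame.iloc[:, 0].to_numpy(dtype=float)
    if axis is None:
        axis = _infer_axis(ppm)
    elif axis.n_bins != len(ppm):
        raise ValueError("table row count disagrees with the supplied axis")
    return [
        Spectrum(axis, frame[col].to_numpy(dtype=float), label=str(col))
        for col in frame.columns[1:]
    ]
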