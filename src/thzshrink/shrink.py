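"""Interval-based threshold selection, hard shrinkage, and peak retrieval.

The shrinkage threshold for each kept level is the largest coefficient
magnitude inside fixed "noise and scattering" frequency windows —
spectral intervals that contain no resonant line, so whatever lives
there at a given scale is artifact.  Coefficients below that level-wise
threshold are zeroed (hard thresholding); excluded levels are zeroed
outright; the scaling coefficients (baseline) pass through untouched.
After reversing the zero-phase advances, the inverse pyramid yields a
reconstructed derivative spectrum in which the surviving local maxima
mark the resonant frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .modwt import WaveletDecomposition, modwt_inverse, unalign
from .spectra import Spectrum

__all__ = [
    "ThresholdSet",
    "Peak",
    "PeakList",
    "compute_thresholds",
    "hard_threshold",
    "reconstruct",
    "find_resonances",
    "DEFAULT_WINDOWS",
]

log = logging.getLogger(__name__)

#: Default noise/scattering windows: 200 GHz wide, centered at 0.3 and 1.7 THz.
DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = ((0.3, 0.2), (1.7, 0.2))


@dataclass(frozen=True)
class ThresholdSet:
    """Per-level hard thresholds and the windows they were read from."""

    tau: dict[int, float]
    windows: tuple[tuple[float, float], ...]
    source_index_ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.tau.values()):
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class Peak:
    frequency: float  # THz
    amplitude: float
    prominence: float


@dataclass(frozen=True)
class PeakList:
    """Detected resonance candidates, sorted by frequency."""

    peaks: tuple[Peak, ...]
    prominence_floor: float
    matches: dict[float, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        freqs = [p.frequency for p in self.peaks]
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("peak frequencies must be strictly increasing")
        if any(p.amplitude <= 0 for p in self.peaks):
            raise ValueError("peak amplitudes must be positive")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([p.frequency for p in self.peaks])

    def dominant(self) -> Peak:
        """The largest-amplitude peak."""
        if not self.peaks:
            raise ValueError("no peaks detected")
        return max(self.peaks, key=lambda p: p.amplitude)

    def match(self, centers, tol: float = 0.02) -> "PeakList":
        """Associate each reference line center with the nearest peak within ``tol`` THz."""
        matches: dict[float, float | None] = {}
        for c in centers:
            c = float(getattr(c, "center", c))
            if len(self.peaks) == 0:
                matches[c] = None
                continue
            devs = np.abs(self.frequencies - c)
            i = int(np.argmin(devs))
            matches[c] = float(self.frequencies[i]) if devs[i] <= tol else None
        return PeakList(self.peaks, self.prominence_floor, matches)

    def to_frame(self) -> pd.DataFrame:
        inverse = {v: k for k, v in self.matches.items() if v is not None}
        return pd.DataFrame(
            {
                "frequency_THz": [p.frequency for p in self.peaks],
                "amplitude": [p.amplitude for p in self.peaks],
                "prominence": [p.prominence for p in self.peaks],
                "matched_line": [inverse.get(p.frequency, np.nan) for p in self.peaks],
            }
        )


def _window_indices(
    freq: np.ndarray, band: tuple[float, float], windows
) -> tuple[tuple[int, int], ...]:
    """Resolve (center, width) windows to inclusive index spans clipped to the band."""
    df = (freq[-1] - freq[0]) / (len(freq) - 1)
    spans = []
    for center, width in windows:
        lo = max(center - width / 2, band[0])
        hi = min(center + width / 2, band[1])
        if hi <= lo + 1e-9:  # clipped to (numerically) nothing
            spans.append(None)
            continue
        i1 = int(np.searchsorted(freq, lo - 0.5 * df))
        i2 = int(np.searchsorted(freq, hi + 0.5 * df)) - 1
        spans.append((i1, i2) if i2 >= i1 else None)
        if lo > center - width / 2 + 1e-12 or hi < center + width / 2 - 1e-12:
            log.warning(
                "threshold window (%.3g, %.3g THz) clipped to band [%.3g, %.3g]",
                center,
                width,
                lo,
                hi,
            )
    return tuple(spans)


def compute_thresholds(
    d: WaveletDecomposition,
    kept: set[int],
    windows=DEFAULT_WINDOWS,
    band: tuple[float, float] | None = None,
) -> ThresholdSet:
    """Per-level thresholds: the largest |coefficient| inside the windows.

    Requires zero-phase aligned coefficients — without the alignment the
    windows would address coefficients belonging to shifted frequencies.
    Windows falling partly outside the band are clipped (with a logged
    warning); if every window is empty the call fails.
    """
    if not d.aligned:
        raise ValueError("compute_thresholds requires zero-phase aligned coefficients")
    freq = d.freq
    if band is None:
        band = d.band if d.band is not None else (float(freq[0]), float(freq[-1]))
    spans = _window_indices(freq, band, windows)
    live = [s for s in spans if s is not None]
    if not live:
        raise ValueError(
            f"every threshold window {tuple(windows)} lies outside the band {band}"
        )
    tau = {}
    for j in sorted(kept):
        tau[j] = float(max(np.max(np.abs(d.W[j][i1 : i2 + 1])) for i1, i2 in live))
    return ThresholdSet(tau=tau, windows=tuple(windows), source_index_ranges=tuple(live))


def hard_threshold(
    d: WaveletDecomposition, tau: ThresholdSet, excluded: set[int] | None = None
) -> WaveletDecomposition:
    """Zero sub-threshold coefficients on kept levels and whole excluded levels.

    Kept-level coefficients with |W| >= tau_j survive verbatim; excluded
    levels are zeroed entirely (reconstruction still needs full-length
    arrays at every level); scaling coefficients pass through.
    """
    if not d.aligned:
        raise ValueError("hard_threshold requires zero-phase aligned coefficients")
    excluded = excluded or set()
    new_W = {}
    for j, w in d.W.items():
        if j in excluded:
            new_W[j] = np.zeros_like(w)
        elif j in tau.tau:
            new_W[j] = np.where(np.abs(w) >= tau.tau[j], w, 0.0)
        else:
            new_W[j] = w
    return d.replace_levels(new_W)


def reconstruct(d: WaveletDecomposition) -> Spectrum:
    """Reverse the zero-phase advances, invert the pyramid, return the spectrum.

    The advances must be undone before inversion because the inverse
    pyramid employs the same filters as the decomposition and assumes
    the raw coefficient phases.
    """
    values = modwt_inverse(unalign(d))
    band = d.band if d.band is not None else (float(d.freq[0]), float(d.freq[-1]))
    return Spectrum(d.freq, values, band, kind="derivative")


def find_resonances(
    s: Spectrum,
    prominence_floor: float = 0.05,
    match_tol: float = 0.02,
    reference=None,
) -> PeakList:
    """Strict positive local maxima of a derivative spectrum.

    A peak must have positive amplitude and prominence at least
    ``prominence_floor`` times the spectrum's in-band dynamic range.
    A flat spectrum yields an empty list.  If ``reference`` line centers
    are given, each is matched to the nearest peak within ``match_tol``.
    """
    if not np.all(np.isfinite(s.values)):
        raise ValueError("spectrum must be finite")
    i1, i2 = s.band_indices()
    y = s.values[i1 : i2 + 1]
    f = s.freq[i1 : i2 + 1]
    dyn = float(np.max(y) - np.min(y))
    if dyn <= 0:
        return PeakList((), prominence_floor)
    floor = prominence_floor * dyn
    idx, props = find_peaks(y, prominence=floor)
    peaks = tuple(
        Peak(float(f[i]), float(y[i]), float(p))
        for i, p in zip(idx, props["prominences"])
        if y[i] > 0
    )
    out = PeakList(peaks, prominence_floor)
    if reference is not None:
        out = out.match(reference, tol=match_tol)
    return out
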