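"""Spectrum containers, file I/O, and preprocessing.

The pipeline operates on frequency-domain power reflectivity spectra
|rho(f)|^2 sampled on a uniform THz grid, or on raw time-domain pulse
traces from which reflectivity is computed against a reference
(typically a flat mirror).  The quantity that seeds the wavelet
analysis is the negative derivative of reflectivity with respect to
frequency, in which absorption resonances appear as antisymmetric
swings about their center frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import io

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "PulseTrace",
    "read_spectrum",
    "write_spectrum",
    "read_pulse_trace",
    "reflectivity_from_traces",
    "negative_derivative",
]

#: Minimum number of samples a spectrum must carry.
MIN_POINTS = 16

#: Relative tolerance on frequency-grid uniformity.
GRID_RTOL = 1e-9

_KINDS = ("reflectivity", "derivative", "extinction")


@dataclass(frozen=True)
class Spectrum:
    """A real-valued spectrum on a uniform frequency axis.

    Parameters
    ----------
    freq : ndarray
        Strictly increasing, uniformly spaced frequencies in THz.
    values : ndarray
        Real values, same length as ``freq``.  Power reflectivity
        values must be non-negative.
    band : (float, float)
        Analysis band limits ``(f1, f2)`` in THz; both must lie
        within the frequency axis.
    kind : str
        One of ``reflectivity``, ``derivative``, ``extinction``.
    """

    freq: np.ndarray
    values: np.ndarray
    band: tuple[float, float]
    kind: str = "reflectivity"

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "values", values)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}; expected one of {_KINDS}")
        if freq.ndim != 1 or values.ndim != 1:
            raise ValueError("freq and values must be one-dimensional")
        if len(freq) != len(values):
            raise ValueError(f"freq has {len(freq)} samples but values has {len(values)}")
        if len(freq) < MIN_POINTS:
            raise ValueError(f"spectrum needs at least {MIN_POINTS} samples, got {len(freq)}")
        steps = np.diff(freq)
        if np.any(steps <= 0):
            raise ValueError("frequency axis must be strictly increasing")
        df = (freq[-1] - freq[0]) / (len(freq) - 1)
        if np.max(np.abs(steps - df)) >= GRID_RTOL * df * len(freq):
            raise ValueError("frequency axis is not uniformly spaced")
        f1, f2 = self.band
        if not (f1 < f2):
            raise ValueError(f"band must satisfy f1 < f2, got {self.band}")
        if f1 < freq[0] - GRID_RTOL * df or f2 > freq[-1] + GRID_RTOL * df:
            raise ValueError(f"band {self.band} exceeds the frequency axis [{freq[0]}, {freq[-1]}]")
        if self.kind == "reflectivity" and np.any(values < 0):
            raise ValueError("reflectivity values must be non-negative")
        if not np.all(np.isfinite(values)):
            raise ValueError("spectrum values must be finite")

    @property
    def n(self) -> int:
        return len(self.freq)

    @property
    def df(self) -> float:
        """Frequency step in THz."""
        return float((self.freq[-1] - self.freq[0]) / (self.n - 1))

    def band_indices(self, band: tuple[float, float] | None = None) -> tuple[int, int]:
        """Inclusive index span ``(i1, i2)`` covering ``band`` (default: own band)."""
        f1, f2 = band if band is not None else self.band
        i1 = int(np.searchsorted(self.freq, f1 - 0.5 * self.df))
        i2 = int(np.searchsorted(self.freq, f2 + 0.5 * self.df)) - 1
        return i1, i2

    def crop(self, band: tuple[float, float] | None = None) -> "Spectrum":
        """Restrict the axis to the analysis band."""
        i1, i2 = self.band_indices(band)
        freq = self.freq[i1 : i2 + 1]
        return Spectrum(freq, self.values[i1 : i2 + 1], (freq[0], freq[-1]), self.kind)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Spectrum":
        return Spectrum(self.freq, values, self.band, kind or self.kind)


@dataclass(frozen=True)
class PulseTrace:
    """A time-domain THz field trace: uniform time axis in ps."""

    time: np.ndarray
    field: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        fld = np.asarray(self.field, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "field", fld)
        if len(time) != len(fld):
            raise ValueError("time and field must have equal length")
        if len(time) < 2:
            raise ValueError("trace needs at least 2 samples")
        steps = np.diff(time)
        dt = (time[-1] - time[0]) / (len(time) - 1)
        if np.any(steps <= 0) or np.max(np.abs(steps - dt)) >= GRID_RTOL * abs(dt) * len(time):
            raise ValueError("time axis must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float((self.time[-1] - self.time[0]) / (len(self.time) - 1))


def _load_two_columns(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a two-column numeric text file; '#'-prefixed lines may carry metadata."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        head = []
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip().lower()] = val.strip()
                continue
            head.append(line)
            break
        rest = head + fh.readlines()
    text = "".join(rest)
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(
        io.StringIO(text), sep=sep, header=None, comment="#", skip_blank_lines=True
    )
    # tolerate a single header row of column names
    if df.shape[0] and not np.issubdtype(df.dtypes.iloc[0], np.number):
        try:
            float(df.iloc[0, 0])
        except (TypeError, ValueError):
            df = df.iloc[1:].reset_index(drop=True)
    arr = df.iloc[:, :2].astype(float).to_numpy()
    return arr[:, 0], arr[:, 1], meta


def read_spectrum(
    path: str | Path,
    *,
    unit: str = "THz",
    kind: str | None = None,
    band: tuple[float, float] | None = None,
) -> Spectrum:
    """Read a spectrum from two-column CSV/TSV text.

    Optional ``# kind: ...`` / ``# band: f1 f2`` / ``# unit: ...`` comment
    lines are honoured; explicit keyword arguments win.  ``unit`` may be
    THz or GHz; GHz axes are normalised to THz.
    """
    freq, values, meta = _load_two_columns(path)
    unit = (unit or meta.get("unit", "THz")).strip()
    if unit.lower() == "ghz":
        freq = freq / 1000.0
    elif unit.lower() != "thz":
        raise ValueError(f"unsupported frequency unit {unit!r}; use THz or GHz")
    if kind is None:
        kind = meta.get("kind", "reflectivity")
    if band is None:
        if "band" in meta:
            parts = meta["band"].replace(",", " ").split()
            band = (float(parts[0]), float(parts[1]))
        else:
            band = (float(freq[0]), float(freq[-1]))
    if len(freq) != len(np.unique(freq)):
        raise ValueError(f"{path}: frequency axis contains duplicate values")
    return Spectrum(freq, values, band, kind)


def write_spectrum(path: str | Path, s: Spectrum) -> None:
    """Write a spectrum as CSV with a metadata comment header."""
    with open(path, "w") as fh:
        fh.write(f"# kind: {s.kind}\n")
        fh.write(f"# band: {s.band[0]:.9g} {s.band[1]:.9g}\n")
        fh.write("# unit: THz\n")
        for f, v in zip(s.freq, s.values):
            fh.write(f"{f:.12g},{v:.12g}\n")


def read_pulse_trace(path: str | Path) -> PulseTrace:
    """Read a time-domain trace (time_ps, field) from CSV/TSV text."""
    time, fld, _ = _load_two_columns(path)
    return PulseTrace(time, fld)


def reflectivity_from_traces(
    sample: PulseTrace,
    reference: PulseTrace,
    *,
    window: str | None = None,
    pad: int = 0,
    band: tuple[float, float] | None = None,
    floor: float = 1e-6,
) -> Spectrum:
    """Power reflectivity |rho(f)|^2 = |F{sample}|^2 / |F{reference}|^2.

    Both traces must share the time step.  ``window`` names a scipy taper
    (e.g. ``hann``) applied to both traces; ``pad`` appends that many
    zeros before transforming.  The result is restricted to ``band``
    (default: the full positive-frequency grid minus DC).

    Raises
    ------
    ValueError
        If the reference magnitude falls below ``floor`` times its peak
        anywhere inside the band (named by the first failing frequency).
    """
    if abs(sample.dt - reference.dt) > GRID_RTOL * reference.dt:
        raise ValueError("sample and reference traces must share the time step")
    n = max(len(sample.field), len(reference.field)) + max(pad, 0)
    ys, yr = sample.field, reference.field
    if window is not None:
        from scipy.signal import get_window

        ys = ys * get_window(window, len(ys))
        yr = yr * get_window(window, len(yr))
    fs = np.fft.rfft(ys, n)
    fr = np.fft.rfft(yr, n)
    freq = np.fft.rfftfreq(n, d=sample.dt)  # ps -> THz
    if band is None:
        band = (float(freq[1]), float(freq[-1]))
    keep = (freq >= band[0] - GRID_RTOL) & (freq <= band[1] + GRID_RTOL)
    ref_mag = np.abs(fr[keep])
    bad = ref_mag < floor * np.max(np.abs(fr))
    if np.any(bad):
        f_bad = freq[keep][bad][0]
        raise ValueError(f"reference spectrum magnitude below floor at {f_bad:.4f} THz")
    vals = np.abs(fs[keep]) ** 2 / ref_mag**2
    f = freq[keep]
    return Spectrum(f, vals, (f[0], f[-1]), "reflectivity")


def negative_derivative(s: Spectrum) -> Spectrum:
    """Negative frequency derivative -d|rho(f)|^2/df of a reflectivity spectrum.

    Central differences in the interior, one-sided at the ends; the axis
    and analysis band are preserved.  This is the signal the wavelet
    pyramid decomposes: each absorption dip becomes an antisymmetric
    feature with its positive lobe just below the line center.
    """
    if s.kind != "reflectivity":
        raise ValueError(f"negative_derivative expects a reflectivity spectrum, got kind={s.kind!r}")
    if s.n < 3:
        raise ValueError("need at least 3 samples to differentiate")
    deriv = -np.gradient(s.values, s.df)
    return s.with_values(deriv, kind="derivative")
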