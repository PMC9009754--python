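"""Maximal overlap discrete wavelet transform (MODWT).

The MODWT is the undecimated, shift-equivariant variant of the discrete
wavelet transform.  The forward pyramid computes, for level j,

    W_j(t) = sum_k h(k) V_{j-1}((t - 2^{j-1} k) mod N)
    V_j(t) = sum_k g(k) V_{j-1}((t - 2^{j-1} k) mod N)

with V_0 the input signal, h and g the MODWT wavelet and scaling
filters (orthonormal filters divided by sqrt(2)), and circular boundary
treatment.  The inverse pyramid

    V_{j-1}(t) = sum_k h(k) W_j((t + 2^{j-1} k) mod N)
               + sum_k g(k) V_j((t + 2^{j-1} k) mod N)

reconstructs the signal exactly.  For the least-asymmetric LA(L)
families the filters are nearly linear-phase, so circularly advancing
the level-j wavelet coefficients by |2^{j-1}(L-1) + nu| — with nu the
family phase parameter — aligns wavelet-domain features with the input
signal (an effective zero-phase transform).  This alignment is what
allows shrinkage thresholds to be read off fixed frequency intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import pywt

__all__ = [
    "FilterPair",
    "WaveletDecomposition",
    "la_filters",
    "modwt_forward",
    "modwt_inverse",
    "align",
    "unalign",
    "advance_amount",
]

SUPPORTED_LENGTHS = (8, 10, 12, 14, 16, 18, 20)

_FILTER_TOL = 1e-10


def _phase_parameter(L: int) -> int:
    """LA(L) phase parameter nu."""
    if L in (8, 12, 16, 20):
        return -L // 2 + 1
    if L in (10, 18):
        return -L // 2
    if L == 14:
        return -L // 2 + 2
    raise ValueError(f"unsupported filter length {L}; supported: {SUPPORTED_LENGTHS}")


@dataclass(frozen=True)
class FilterPair:
    """MODWT wavelet/scaling filter pair for a least-asymmetric family.

    ``h`` is the wavelet (highpass) filter with zero sum, ``g`` the
    scaling (lowpass) filter summing to one; both carry energy 1/2.
    ``nu`` is the phase parameter used by the zero-phase alignment.
    """

    h: np.ndarray
    g: np.ndarray
    family: str
    nu: int

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "g", g)
        L = len(h)
        if len(g) != L:
            raise ValueError("wavelet and scaling filters must share the length")
        checks = {
            "sum(h) = 0": abs(h.sum()),
            "sum(g) = 1": abs(g.sum() - 1.0),
            "energy(h) = 1/2": abs((h**2).sum() - 0.5),
            "energy(g) = 1/2": abs((g**2).sum() - 0.5),
        }
        for n in range(1, L // 2):
            checks[f"even-shift orthogonality n={n}"] = abs(np.dot(h[: L - 2 * n], h[2 * n :]))
        bad = {k: v for k, v in checks.items() if v >= _FILTER_TOL}
        if bad:
            raise ValueError(f"filter invariants violated: {bad}")

    @property
    def L(self) -> int:
        return len(self.h)


def la_filters(L: int = 8) -> FilterPair:
    """Least-asymmetric (symlet) MODWT filters of length ``L``.

    The orthonormal symlet coefficients are taken from PyWavelets and
    rescaled by 1/sqrt(2) to the MODWT normalisation; the wavelet filter
    is derived from the scaling filter by the quadrature-mirror relation
    h(k) = (-1)^k g(L-1-k).  The pair is validated against the filter
    invariants rather than trusted.
    """
    if L not in SUPPORTED_LENGTHS:
        raise ValueError(f"unsupported filter length {L}; supported: {SUPPORTED_LENGTHS}")
    g_ortho = np.asarray(pywt.Wavelet(f"sym{L // 2}").dec_lo, dtype=float)
    g = g_ortho / np.sqrt(2.0)
    k = np.arange(L)
    h = (-1.0) ** k * g[::-1]
    return FilterPair(h=h, g=g, family=f"LA({L})", nu=_phase_parameter(L))


def advance_amount(j: int, filters: FilterPair) -> int:
    """Circular advance |2^{j-1}(L-1) + nu| aligning level-j wavelet coefficients.

    This is the phase delay of the effective level-j wavelet filter for
    the least-asymmetric families (nu is negative, so the advance is
    smaller than the filter delay 2^{j-1}(L-1)); it coincides with the
    energy centroid of the cascade impulse response to within a sample.
    For LA(8) the advances at levels 1..5 are 4, 11, 25, 53, 109.
    """
    return abs(2 ** (j - 1) * (filters.L - 1) + filters.nu)


@dataclass(frozen=True)
class WaveletDecomposition:
    """Per-level MODWT coefficients of a single signal.

    ``W[j]`` holds the level-j wavelet coefficients (length N each),
    ``V`` the level-J scaling coefficients.  ``advances[j]`` records the
    circular advance currently applied to ``W[j]``: 0 when raw, the
    zero-phase amount after :func:`align`.  Scaling coefficients are
    never advanced.  ``freq`` carries the originating frequency axis so
    band-restricted diagnostics can resolve indices.
    """

    W: dict[int, np.ndarray]
    V: np.ndarray
    J: int
    filters: FilterPair
    advances: dict[int, int]
    freq: np.ndarray
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        n = len(self.V)
        if self.J > int(np.floor(np.log2(n))):
            raise ValueError(f"depth J={self.J} too deep for N={n} samples")
        if sorted(self.W) != list(range(1, self.J + 1)):
            raise ValueError("W must hold levels 1..J")
        for j, w in self.W.items():
            if len(w) != n:
                raise ValueError(f"level {j} has length {len(w)}, expected {n}")
            if self.advances.get(j) not in (0, advance_amount(j, self.filters)):
                raise ValueError(f"level {j} carries an unexpected advance {self.advances.get(j)}")
        if len(self.freq) != n:
            raise ValueError("frequency axis length must match coefficient length")

    @property
    def n(self) -> int:
        return len(self.V)

    @property
    def aligned(self) -> bool:
        return all(self.advances[j] != 0 for j in self.W)

    @property
    def raw(self) -> bool:
        return all(self.advances[j] == 0 for j in self.W)

    def replace_levels(self, new_W: dict[int, np.ndarray]) -> "WaveletDecomposition":
        W = {j: np.array(new_W.get(j, w), dtype=float) for j, w in self.W.items()}
        return replace(self, W=W)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table of all coefficients (one row per level/sample)."""
        rows = []
        for j in range(1, self.J + 1):
            rows.append(
                pd.DataFrame(
                    {
                        "level": f"W{j}",
                        "freq_THz": self.freq,
                        "coefficient": self.W[j],
                        "advance": self.advances[j],
                    }
                )
            )
        rows.append(
            pd.DataFrame(
                {"level": f"V{self.J}", "freq_THz": self.freq, "coefficient": self.V, "advance": 0}
            )
        )
        return pd.concat(rows, ignore_index=True)


def _circular_filter(x: np.ndarray, taps: np.ndarray, stride: int, sign: int) -> np.ndarray:
    """sum_k taps[k] * x((t - sign*stride*k) mod N)."""
    n = len(x)
    out = np.zeros(n)
    for k, c in enumerate(taps):
        out += c * np.roll(x, sign * (stride * k) % n)
    return out


def modwt_forward(
    x: np.ndarray,
    filters: FilterPair | None = None,
    J: int = 6,
    freq: np.ndarray | None = None,
    band: tuple[float, float] | None = None,
) -> WaveletDecomposition:
    """Forward MODWT pyramid to depth ``J`` with circular boundaries."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input signal must be finite")
    filters = filters or la_filters(8)
    n = len(x)
    if J > int(np.floor(np.log2(n))):
        raise ValueError(f"depth J={J} exceeds floor(log2(N))={int(np.floor(np.log2(n)))} for N={n}")
    if freq is None:
        freq = np.arange(n, dtype=float)
    W: dict[int, np.ndarray] = {}
    v = x
    for j in range(1, J + 1):
        stride = 2 ** (j - 1)
        W[j] = _circular_filter(v, filters.h, stride, sign=+1)
        v = _circular_filter(v, filters.g, stride, sign=+1)
    return WaveletDecomposition(
        W=W,
        V=v,
        J=J,
        filters=filters,
        advances={j: 0 for j in W},
        freq=np.asarray(freq, dtype=float),
        band=band,
    )


def modwt_inverse(d: WaveletDecomposition) -> np.ndarray:
    """Inverse MODWT pyramid; requires raw (unaligned) coefficients."""
    if not d.raw:
        raise ValueError(
            "decomposition still carries zero-phase advances; call unalign() before inversion"
        )
    v = d.V
    for j in range(d.J, 0, -1):
        stride = 2 ** (j - 1)
        v = _circular_filter(d.W[j], d.filters.h, stride, sign=-1) + _circular_filter(
            v, d.filters.g, stride, sign=-1
        )
    return v


def align(d: WaveletDecomposition) -> WaveletDecomposition:
    """Apply the zero-phase circular advance to every wavelet level.

    Level j is advanced (indices decreased) by ``2^{j-1}(L-1) - nu`` so
    wavelet-domain features line up with the input signal.  Scaling
    coefficients are left untouched.
    """
    if not d.raw:
        raise ValueError("decomposition is already aligned")
    W = {}
    advances = {}
    for j, w in d.W.items():
        adv = advance_amount(j, d.filters)
        W[j] = np.roll(w, -adv)
        advances[j] = adv
    return replace(d, W=W, advances=advances)


def unalign(d: WaveletDecomposition) -> WaveletDecomposition:
    """Exactly reverse :func:`align`."""
    if not d.aligned:
        raise ValueError("decomposition is not aligned")
    W = {j: np.roll(w, d.advances[j]) for j, w in d.W.items()}
    return replace(d, W=W, advances={j: 0 for j in d.W})
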