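"""Decomposition-level diagnostics and the level-exclusion rule.

Sharp scattering artifacts and water-vapor lines dominate the
fine-scale wavelet levels, while the baseline occupies the coarsest
ones.  The second-order total variation (TV2) of each level's
coefficients — the band-restricted sum of absolute second differences —
separates levels carrying resonance-scale structure from both extremes
far more cleanly than the per-level energy does.  Levels whose TV2
fraction is above ``upper`` (noise/artifact-dominated) or below
``lower`` (baseline-only) are excluded before shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modwt import WaveletDecomposition

__all__ = ["LevelProfile", "tv2_per_level", "select_levels"]

#: Default exclusion bounds on the TV2 fraction per level.
TV_UPPER = 0.25
TV_LOWER = 0.002


@dataclass(frozen=True)
class LevelProfile:
    """Per-level TV2 and energy, with copies normalised to sum to one."""

    tv2: dict[int, float]
    energy: dict[int, float]
    tv2_fraction: dict[int, float]
    energy_fraction: dict[int, float]
    band: tuple[float, float]

    def __post_init__(self) -> None:
        for name, m in (("tv2", self.tv2), ("energy", self.energy)):
            if any(v < 0 for v in m.values()):
                raise ValueError(f"{name} entries must be non-negative")
        for name, m in (("tv2_fraction", self.tv2_fraction), ("energy_fraction", self.energy_fraction)):
            if abs(sum(m.values()) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1")

    def to_frame(self, kept: set[int] | None = None) -> pd.DataFrame:
        levels = sorted(self.tv2)
        return pd.DataFrame(
            {
                "level": levels,
                "tv2": [self.tv2[j] for j in levels],
                "energy": [self.energy[j] for j in levels],
                "tv2_fraction": [self.tv2_fraction[j] for j in levels],
                "energy_fraction": [self.energy_fraction[j] for j in levels],
                "kept": [j in kept if kept is not None else None for j in levels],
            }
        )


def tv2_per_level(
    d: WaveletDecomposition, band: tuple[float, float] | None = None
) -> LevelProfile:
    """Second-order total variation and energy of each wavelet level.

    The decomposition must be zero-phase aligned so the band indices
    address the coefficients that actually live at those frequencies.
    With in-band coefficients w(f1), ..., w(f2), the first differences
    D1(f) = w(f + df) - w(f) and second differences
    D2(f) = D1(f + df) - D1(f) give TV2 = sum |D2(f)| for f in
    [f1, f2 - 2*df].  Energy is the in-band sum of squares.
    """
    if not d.aligned:
        raise ValueError("tv2_per_level requires zero-phase aligned coefficients")
    freq = d.freq
    if band is None:
        band = d.band if d.band is not None else (float(freq[0]), float(freq[-1]))
    df = (freq[-1] - freq[0]) / (len(freq) - 1)
    i1 = int(np.searchsorted(freq, band[0] - 0.5 * df))
    i2 = int(np.searchsorted(freq, band[1] + 0.5 * df)) - 1
    if i2 - i1 + 1 < 3:
        raise ValueError("analysis band must cover at least 3 samples")
    tv2 = {}
    energy = {}
    for j in range(1, d.J + 1):
        w = d.W[j][i1 : i2 + 1]
        tv2[j] = float(np.abs(np.diff(w, n=2)).sum())
        energy[j] = float((w**2).sum())
    tv_total = sum(tv2.values())
    en_total = sum(energy.values())
    # a featureless (all-zero) band degenerates to uniform fractions so a
    # null input flows through selection and yields an empty peak list
    tv2_frac = (
        {j: v / tv_total for j, v in tv2.items()}
        if tv_total > 0
        else {j: 1.0 / d.J for j in tv2}
    )
    en_frac = (
        {j: v / en_total for j, v in energy.items()}
        if en_total > 0
        else {j: 1.0 / d.J for j in energy}
    )
    return LevelProfile(
        tv2=tv2, energy=energy, tv2_fraction=tv2_frac, energy_fraction=en_frac, band=band
    )


def select_levels(
    p: LevelProfile, upper: float = TV_UPPER, lower: float = TV_LOWER
) -> tuple[set[int], dict[int, str]]:
    """Keep levels whose TV2 fraction lies within [lower, upper].

    Returns the kept level set and, for the excluded levels, the reason
    ("above upper bound" for artifact-dominated levels, "below lower
    bound" for baseline-only ones).  Both comparisons are inclusive.
    The level-J scaling coefficients are outside this rule entirely:
    they carry the baseline and are never excluded.
    """
    kept: set[int] = set()
    reasons: dict[int, str] = {}
    for j, frac in p.tv2_fraction.items():
        if frac > upper:
            reasons[j] = f"tv2 fraction {frac:.4g} above upper bound {upper}"
        elif frac < lower:
            reasons[j] = f"tv2 fraction {frac:.4g} below lower bound {lower}"
        else:
            kept.add(j)
    if not kept:
        raise ValueError(
            "level selection excluded every decomposition level; "
            "review the analysis band and the TV2 bounds"
        )
    return kept, reasons
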