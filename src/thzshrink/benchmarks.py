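"""Simulation studies used to benchmark the shrinkage pipeline.

These routines run the identification pipeline on seeded synthetic
scenarios and score the recovered peaks against the generating line
lists.  They exist so the same study definitions are shared between the
test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .pipeline import PipelineConfig, run_identify
from .synth import Line, Scenario, preset

__all__ = [
    "random_three_line_scenario",
    "matched_peak_deviations",
    "line_recovery_rates",
    "least_recovered_line",
]


def random_three_line_scenario(seed: int) -> Scenario:
    """A grit-220-like rough-surface spectrum with three random modes.

    Centers are drawn uniformly in 0.4-1.5 THz with at least 0.15 THz
    separation, depths in 0.3-0.8, FWHMs in 25-40 GHz; the surface has
    16 um RMS height at 35 degrees incidence and the trace carries
    30 dB additive noise on a 5 GHz grid over 0.2-1.8 THz.
    """
    rng = np.random.default_rng(seed)
    while True:
        centers = np.sort(rng.uniform(0.4, 1.5, 3))
        if np.all(np.diff(centers) >= 0.15):
            break
    lines = tuple(
        Line(float(c), float(rng.uniform(0.3, 0.8)), float(rng.uniform(0.025, 0.040)))
        for c in centers
    )
    return Scenario(
        lines=lines,
        sigma=16.0,
        theta_i=35.0,
        snr_db=30.0,
        water_vapor=False,
        delta_f=0.005,
        band=(0.2, 1.8),
        seed=seed,
    )


def matched_peak_deviations(
    peak_freqs: np.ndarray, centers, tol: float = 0.02
) -> list[float]:
    """|recovered - generated| for every peak matched to a line center.

    Each recovered peak is associated with its nearest generating
    center; pairs farther apart than ``tol`` are considered unmatched
    and do not contribute.
    """
    centers = np.asarray([float(getattr(c, "center", c)) for c in centers])
    devs = []
    for p in np.asarray(peak_freqs, dtype=float):
        d = float(np.min(np.abs(centers - p)))
        if d <= tol:
            devs.append(d)
    return devs


def line_recovery_rates(
    material: str,
    grit: int,
    seeds,
    tol: float = 0.02,
    config: PipelineConfig | None = None,
) -> dict[float, float]:
    """Fraction of noise realizations in which each mode is recovered.

    Runs the identify pipeline on the preset scenario once per seed and
    counts, for each generated line center, how often a peak lands
    within ``tol`` THz of it.
    """
    seeds = list(seeds)
    sc0 = preset(material, grit, seed=seeds[0])
    hits = {line.center: 0 for line in sc0.lines}
    for s in seeds:
        res = run_identify(preset(material, grit, seed=s), config)
        freqs = res.peaks.frequencies
        for line in sc0.lines:
            if len(freqs) and np.min(np.abs(freqs - line.center)) <= tol:
                hits[line.center] += 1
    return {c: h / len(seeds) for c, h in hits.items()}


def least_recovered_line(rates: dict[float, float]) -> float:
    """Center of the mode with the lowest recovery rate (ties: lowest center)."""
    return min(sorted(rates), key=lambda c: rates[c])
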