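"""Seeded synthetic rough-surface THz reflectivity generator.

No measured spectra ship with this package, so testing and benchmarking
run on synthetic reflectivities that emulate what a reflection-mode
THz-TDS instrument sees from a pressed molecular-crystal pellet with a
controlled rough surface:

* a Fresnel baseline ``r2`` times the Kirchhoff/Rayleigh Gaussian
  frequency roll-off set by the RMS surface height;
* multiplicative Lorentzian absorption dips at the material's resonant
  line centers;
* sharp Gaussian atmospheric water-vapor absorption lines;
* an angle-dependent loss lobe emulating the amplitude and bandwidth
  collapse seen at off-specular detection angles;
* seeded additive white Gaussian noise, floored at a small positive
  reflectivity.

Presets reproduce the study's conditions: alpha-lactose monohydrate
(lines at 0.53, 1.2, 1.38 THz, the 1.2 THz mode being the weakest and
narrowest) and 4-aminobenzoic acid (PABA; 0.6, 0.8, 1.29, 1.54 THz),
each pressed against sandpaper of grit 220/120/80/40 whose fitted RMS
heights are tabulated below, measured at 35 degrees incidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .scatter import C_UM_PS, KirchhoffModel
from .spectra import Spectrum

__all__ = [
    "Line",
    "Scenario",
    "synth_reflectivity",
    "preset",
    "angular_lobe",
    "LACTOSE_LINES",
    "PABA_LINES",
    "WATER_VAPOR_LINES",
    "FITTED_SIGMA_UM",
    "LITERATURE_SIGMA_UM",
]


@dataclass(frozen=True)
class Line:
    """A resonant absorption mode: center (THz), fractional depth, FWHM (THz)."""

    center: float
    depth: float
    fwhm: float

    def __post_init__(self) -> None:
        if not (0 < self.depth < 1):
            raise ValueError("depth must lie in (0, 1)")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")


# Default line lists.  Centers are the materials' published resonant
# frequencies; depths and widths are generator choices shaped so that
# the lactose 1.2 THz mode is the weakest and narrowest of its set.
LACTOSE_LINES: tuple[Line, ...] = (
    Line(0.53, 0.8, 0.025),
    Line(1.2, 0.15, 0.015),
    Line(1.38, 0.6, 0.030),
)
PABA_LINES: tuple[Line, ...] = (
    Line(0.6, 0.5, 0.030),
    Line(0.8, 0.6, 0.030),
    Line(1.29, 0.5, 0.035),
    Line(1.54, 0.35, 0.040),
)

#: Sharp atmospheric water-vapor absorption lines (THz), injected as
#: Gaussian dips of 5 GHz FWHM and depth 0.5 when enabled.
WATER_VAPOR_LINES: tuple[float, ...] = (0.557, 0.752, 1.097, 1.163, 1.41)
WATER_VAPOR_FWHM = 0.005
WATER_VAPOR_DEPTH = 0.5

#: RMS surface heights (um) obtained from Kirchhoff fits for each
#: sandpaper grit, per material, alongside the literature values for
#: the sandpapers themselves.
FITTED_SIGMA_UM: dict[str, dict[int, float]] = {
    "lactose": {220: 16.0, 120: 26.0, 80: 44.0, 40: 93.0},
    "paba": {220: 15.0, 120: 22.0, 80: 40.0, 40: 91.0},
}
LITERATURE_SIGMA_UM: dict[int, float] = {220: 15.0, 120: 21.0, 80: 55.0, 40: 135.0}

_MATERIAL_LINES = {"lactose": LACTOSE_LINES, "paba": PABA_LINES}

#: Width of the off-specular loss lobe in radians at k*sigma = 1; the
#: lobe narrows with frequency and roughness, emulating the bandwidth
#: collapse observed away from the specular angle.  A heuristic, not a
#: physical-optics result.
LOBE_SCALE_RAD = 0.2


@dataclass(frozen=True)
class Scenario:
    """Full description of one synthetic measurement."""

    lines: tuple[Line, ...]
    sigma: float = 15.0  # um RMS surface height
    theta_i: float = 35.0  # deg incidence from normal
    detection_offset: float = 0.0  # deg away from specular
    r2: float = 0.3  # Fresnel baseline
    snr_db: float | None = 30.0  # additive noise level; None = noiseless
    noise_floor: float | None = None  # default 1e-3 * r2
    water_vapor: bool = True
    delta_f: float = 0.005  # THz
    band: tuple[float, float] = (0.2, 1.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_f <= 0:
            raise ValueError("delta_f must be positive")
        if self.band[0] >= self.band[1]:
            raise ValueError("band must satisfy f1 < f2")
        if self.detection_offset < 0:
            raise ValueError("detection_offset must be non-negative")
        for ln in self.lines:
            if not (self.band[0] < ln.center < self.band[1]):
                raise ValueError(f"line center {ln.center} THz outside band {self.band}")

    def frequency_axis(self) -> np.ndarray:
        f1, f2 = self.band
        n = int(round((f2 - f1) / self.delta_f)) + 1
        axis = f1 + self.delta_f * np.arange(n)
        if abs(axis[-1] - f2) > 1e-9 * self.delta_f:
            raise ValueError(f"band {self.band} is not an integer number of delta_f steps")
        return axis


def _lorentzian(f: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    return 1.0 / (1.0 + ((f - center) / (fwhm / 2.0)) ** 2)


def _gaussian(f: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-((f - center) ** 2) / (2.0 * s**2))


def angular_lobe(freq: np.ndarray, offset_deg: float, sigma_um: float) -> np.ndarray:
    """Off-specular amplitude loss factor in (0, 1].

    Gaussian in the detection offset with a frequency-dependent angular
    width proportional to 1/(k*sigma): rougher surfaces and higher
    frequencies concentrate less energy away from specular, so the
    high-frequency end of the band collapses first as the detector
    moves off the mirror angle.  At offset 0 (specular) the factor is
    identically 1, as it is for a smooth surface (sigma = 0).
    """
    if offset_deg == 0 or sigma_um == 0:
        return np.ones_like(np.asarray(freq, dtype=float))
    k = 2.0 * np.pi * np.asarray(freq, dtype=float) / C_UM_PS  # rad/um
    width = LOBE_SCALE_RAD / (k * sigma_um)  # radians
    return np.exp(-0.5 * (np.radians(offset_deg) / width) ** 2)


def synth_reflectivity(sc: Scenario) -> Spectrum:
    """Generate the scenario's power reflectivity spectrum.

    Deterministic for a fixed scenario (the seed is part of it).
    """
    f = sc.frequency_axis()
    model = KirchhoffModel(sigma=sc.sigma, theta_i=sc.theta_i, r2=sc.r2)
    vals = sc.r2 * np.exp(-model.rayleigh_exponent(f))
    vals *= angular_lobe(f, sc.detection_offset, sc.sigma)
    for ln in sc.lines:
        vals *= 1.0 - ln.depth * _lorentzian(f, ln.center, ln.fwhm)
    if sc.water_vapor:
        for center in WATER_VAPOR_LINES:
            if sc.band[0] < center < sc.band[1]:
                vals *= 1.0 - WATER_VAPOR_DEPTH * _gaussian(f, center, WATER_VAPOR_FWHM)
    if sc.snr_db is not None:
        rng = np.random.default_rng(sc.seed)
        noise_sigma = float(np.max(vals)) * 10.0 ** (-sc.snr_db / 20.0)
        vals = vals + rng.normal(0.0, noise_sigma, size=len(f))
    floor = sc.noise_floor if sc.noise_floor is not None else 1e-3 * sc.r2
    vals = np.maximum(vals, floor)
    return Spectrum(f, vals, sc.band, "reflectivity")


def preset(
    material: str,
    grit: int,
    detection_offset: float = 0.0,
    seed: int = 0,
    **overrides,
) -> Scenario:
    """Scenario for a study condition: material x sandpaper grit x angle.

    ``material`` is ``lactose`` or ``paba``; ``grit`` one of
    220/120/80/40; ``detection_offset`` the detection angle away from
    specular in degrees.  The RMS height is the material's fitted value
    for that grit; incidence is 35 degrees; remaining fields take the
    Scenario defaults unless overridden.
    """
    mat = material.lower()
    if mat not in _MATERIAL_LINES:
        raise ValueError(f"unknown material {material!r}; choose from {sorted(_MATERIAL_LINES)}")
    if grit not in FITTED_SIGMA_UM[mat]:
        raise ValueError(f"unknown grit {grit}; choose from {sorted(FITTED_SIGMA_UM[mat])}")
    return Scenario(
        lines=_MATERIAL_LINES[mat],
        sigma=FITTED_SIGMA_UM[mat][grit],
        theta_i=35.0,
        detection_offset=detection_offset,
        seed=seed,
        **overrides,
    )
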