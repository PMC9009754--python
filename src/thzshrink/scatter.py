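"""Kirchhoff-approximation rough-surface scattering model.

For a surface with Gaussian height statistics and RMS height sigma,
the Kirchhoff (tangent-plane) approximation predicts that the specular
power reflectivity decays from its Fresnel baseline |r|^2 by the
Rayleigh factor:

    |rho(f)|^2 = |r|^2 exp(-4 k^2 sigma^2 cos^2 theta_i),   k = 2 pi f / c

with theta_i the incidence angle from the surface normal.  Because the
log of the roll-off is linear in k^2, sigma can be estimated from a
measured reflectivity by an ordinary least-squares fit in the log
domain.  The Fraunhofer criterion sigma >= lambda / (32 cos theta_i)
then flags the wavelengths for which the scattering distortion is
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import Spectrum

__all__ = [
    "KirchhoffModel",
    "FitReport",
    "kirchhoff_rolloff",
    "fit_sigma",
    "fraunhofer_threshold",
    "C_UM_PS",
]

#: Speed of light in micrometres per picosecond (so f in THz gives k in rad/um).
C_UM_PS = 299.792458


@dataclass(frozen=True)
class KirchhoffModel:
    """Specular Kirchhoff scattering parameters.

    sigma : RMS surface height in micrometres.
    theta_i : incidence angle in degrees from the surface normal.
    r2 : Fresnel power reflectivity baseline in (0, 1].
    """

    sigma: float
    theta_i: float = 35.0
    r2: float = 0.3

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not (0 <= self.theta_i < 90):
            raise ValueError("theta_i must lie in [0, 90) degrees")
        if not (0 < self.r2 <= 1):
            raise ValueError("r2 must lie in (0, 1]")

    def rayleigh_exponent(self, freq_thz: np.ndarray) -> np.ndarray:
        """4 k^2 sigma^2 cos^2(theta_i), dimensionless."""
        k = 2.0 * np.pi * np.asarray(freq_thz, dtype=float) / C_UM_PS
        return 4.0 * k**2 * self.sigma**2 * np.cos(np.radians(self.theta_i)) ** 2


@dataclass(frozen=True)
class FitReport:
    """Diagnostics of a log-domain Kirchhoff fit."""

    sigma_um: float
    sigma_err_um: float
    r2: float
    slope: float  # d ln|rho|^2 / d k^2, um^2
    residual_rms: float
    band: tuple[float, float]
    n_points: int
    warning: str | None = None

    def summary(self) -> str:
        lines = [
            f"sigma_um: {self.sigma_um:.4g}",
            f"sigma_err_um: {self.sigma_err_um:.3g}",
            f"r2: {self.r2:.4g}",
            f"slope_um2: {self.slope:.4g}",
            f"residual_rms: {self.residual_rms:.3g}",
            f"band_THz: {self.band[0]:.4g} {self.band[1]:.4g}",
            f"n_points: {self.n_points}",
        ]
        if self.warning:
            lines.append(f"warning: {self.warning}")
        return "\n".join(lines)


def kirchhoff_rolloff(m: KirchhoffModel, freq: np.ndarray) -> Spectrum:
    """Specular reflectivity |rho(f)|^2 predicted by the Kirchhoff model."""
    freq = np.asarray(freq, dtype=float)
    values = m.r2 * np.exp(-m.rayleigh_exponent(freq))
    return Spectrum(freq, values, (float(freq[0]), float(freq[-1])), "reflectivity")


def fit_sigma(
    s: Spectrum,
    theta_i: float = 35.0,
    fit_band: tuple[float, float] | None = None,
    floor_frac: float = 0.01,
) -> FitReport:
    """Estimate RMS surface height from a reflectivity spectrum.

    Ordinary least squares of ln|rho|^2 against k^2 over ``fit_band``
    (default: the spectrum's analysis band).  The slope equals
    -4 sigma^2 cos^2(theta_i) and the intercept ln r2, so

        sigma = sqrt(-slope) / (2 cos theta_i).

    Samples below ``floor_frac`` times the in-band maximum are dropped
    to keep the noise floor from biasing the log fit.  A non-negative
    slope (no decay) yields sigma = 0 with a warning diagnostic.
    """
    if s.kind != "reflectivity":
        raise ValueError("fit_sigma expects a reflectivity spectrum")
    i1, i2 = s.band_indices(fit_band)
    f = s.freq[i1 : i2 + 1]
    y = s.values[i1 : i2 + 1]
    keep = y > floor_frac * np.max(y)
    f, y = f[keep], y[keep]
    if np.any(y <= 0):
        raise ValueError("reflectivity must be positive on the fit band")
    band = (float(f[0]), float(f[-1]))
    k2 = (2.0 * np.pi * f / C_UM_PS) ** 2
    res = stats.linregress(k2, np.log(y))
    cos_t = np.cos(np.radians(theta_i))
    resid = np.log(y) - (res.intercept + res.slope * k2)
    rms = float(np.sqrt(np.mean(resid**2)))
    if res.slope >= 0:
        return FitReport(
            sigma_um=0.0,
            sigma_err_um=float("nan"),
            r2=float(np.exp(res.intercept)),
            slope=float(res.slope),
            residual_rms=rms,
            band=band,
            n_points=len(f),
            warning="non-negative slope: no measurable roll-off, sigma set to 0",
        )
    sigma = float(np.sqrt(-res.slope) / (2.0 * cos_t))
    # first-order error propagation through sigma = sqrt(-slope)/(2 cos)
    err = float(res.stderr / (2.0 * np.sqrt(-res.slope)) / (2.0 * cos_t)) if res.stderr else 0.0
    return FitReport(
        sigma_um=sigma,
        sigma_err_um=err,
        r2=float(np.exp(res.intercept)),
        slope=float(res.slope),
        residual_rms=rms,
        band=band,
        n_points=len(f),
    )


def fraunhofer_threshold(sigma: float, theta_i: float = 35.0) -> tuple[float, float]:
    """Fraunhofer roughness criterion: (lambda_threshold um, freq_threshold GHz).

    Scattering is significant for wavelengths below
    lambda_th = 32 sigma cos(theta_i), i.e. frequencies above
    f_th = c / lambda_th.  A perfectly smooth surface (sigma = 0) never
    triggers the criterion; the threshold is returned as infinity.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return float("inf"), float("inf")
    lam = 32.0 * sigma * np.cos(np.radians(theta_i))  # um
    f_ghz = C_UM_PS / lam * 1e3  # THz -> GHz
    return float(lam), float(f_ghz)
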