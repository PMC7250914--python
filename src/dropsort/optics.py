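"""Imaging-constraint calculators for the sorting rig.

All lengths are handled internally in microns and times in seconds; the
reporting layer converts to mm/s, Hz or pL where those are the customary
units.

The calculators cover the rate-limiting steps of image-activated
sorting:

* blur-limited flow velocity V_max = s_p / t_e (one pixel of travel per
  exposure),
* the Berek depth of focus DOF = lambda / (2 NA^2) + RP / (NA * M),
* the actuation-duration throughput ceiling 1 / t_pulse,
* Gaussian FWHM fitting of a laser-spot line profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass
class OpticsConfig:
    """Optical parameters of one imaging path.

    ``resolving_power_um`` is the conventional 340 um visual resolving
    power used in the Berek depth-of-focus estimate.
    """

    pixel_size_um: float = 0.25
    exposure_time_s: float = 250e-6
    wavelength_um: float = 0.47
    numerical_aperture: float = 0.5
    magnification: float = 40.0
    resolving_power_um: float = 340.0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "exposure_time_s", "wavelength_um",
                     "numerical_aperture", "magnification"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.resolving_power_um < 0:
            raise ValueError("resolving_power_um must be non-negative")
        if self.numerical_aperture > 1.7:
            raise ValueError("numerical aperture above 1.7 is unphysical here")


def max_velocity(pixel_size_um: float, exposure_time_s: float) -> float:
    """Blur-free velocity ceiling in um/s: at most one pixel per exposure."""
    if pixel_size_um <= 0 or exposure_time_s <= 0:
        raise ValueError("pixel size and exposure time must be positive")
    return pixel_size_um / exposure_time_s


def depth_of_focus(cfg: OpticsConfig) -> float:
    """Berek depth of focus in microns (wave term + geometric term)."""
    na, m = cfg.numerical_aperture, cfg.magnification
    if na <= 0 or m <= 0:
        raise ValueError("NA and magnification must be positive")
    return cfg.wavelength_um / (2.0 * na**2) + cfg.resolving_power_um / (na * m)


def throughput_ceiling(actuation_duration_s: float) -> float:
    """Maximum sorting rate in Hz set by the actuation pulse duration."""
    if actuation_duration_s <= 0:
        raise ValueError("actuation duration must be positive")
    return 1.0 / actuation_duration_s


def _gaussian(x, amp, mu, sigma, offset):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + offset


def fit_fwhm(profile, pixel_size_um: float) -> float:
    """Least-squares Gaussian fit of a 1-D intensity profile -> FWHM in um.

    Initialisation is deterministic: peak position/height from the
    argmax, width from the second moment of the baseline-subtracted
    profile.  A flat (degenerate) profile raises ``ValueError``.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ValueError("profile must be a 1-D array with at least 5 samples")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    baseline = float(y.min())
    span = float(y.max() - baseline)
    if span <= 0 or span < 1e-9 * max(1.0, abs(baseline)):
        raise ValueError("degenerate (flat) profile: no peak to fit")
    x = np.arange(y.size, dtype=float)
    w = y - baseline
    mu0 = float(np.argmax(y))
    sigma0 = math.sqrt(max(float(np.sum(w * (x - mu0) ** 2) / np.sum(w)), 0.25))
    popt, _ = curve_fit(_gaussian, x, y, p0=[span, mu0, sigma0, baseline],
                        maxfev=10000)
    sigma_px = abs(popt[2])
    return FWHM_PER_SIGMA * sigma_px * pixel_size_um
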