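"""Apparent vesicle size from 1D intensity line profiles.

Size is the standard deviation sigma of a 1D Gaussian fitted to the
intensity profile along the microscope's x-axis through the vesicle
centre; fits with R^2 <= 0.75 are discarded.  FWHM (2*sqrt(2 ln 2)*sigma)
is reported alongside sigma because apparent spot sizes are conventionally
compared with FWHM-like resolution limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class SizeMeasurement:
    vesicle_id: int
    channel_name: str
    sigma_nm: float
    r_squared: float
    accepted: bool

    @property
    def fwhm_nm(self) -> float:
        return FWHM_FACTOR * self.sigma_nm


def line_profile(
    grid, centre_nm: Sequence[float], half_length_px: int = 7
) -> tuple[np.ndarray, np.ndarray]:
    """Sample intensities along x through the voxel row nearest the centre.

    Returns ``(x_nm, intensity)`` with x-coordinates in nm relative to the
    vesicle centre.  No sub-pixel interpolation: the nearest (z, y) row is
    used and samples sit at voxel x-positions.  The profile is clipped at
    the volume borders.
    """
    voxel = grid.voxel_sizes_nm()
    centre_px = np.asarray(centre_nm, dtype=float) / voxel
    z, y = int(round(centre_px[0])), int(round(centre_px[1]))
    z = int(np.clip(z, 0, grid.shape[0] - 1))
    y = int(np.clip(y, 0, grid.shape[1] - 1))
    xc = int(round(centre_px[2]))
    x_lo = max(xc - half_length_px, 0)
    x_hi = min(xc + half_length_px + 1, grid.shape[2])
    xs = np.arange(x_lo, x_hi)
    intensity = grid.data[z, y, x_lo:x_hi].astype(float)
    x_nm = xs * grid.voxel_xy_nm - float(centre_nm[2])
    return x_nm, intensity


def fit_profile(
    x_nm: np.ndarray, intensity: np.ndarray, r2_min: float = 0.75
) -> tuple[float, float, bool]:
    """Fit amplitude * Gaussian(x; mu, sigma) + offset to one profile.

    Returns ``(sigma_nm, r_squared, accepted)``; the fit is accepted iff
    R^2 > r2_min.  Degenerate (flat) profiles are rejected with R^2 = 0.
    """
    x = np.asarray(x_nm, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if len(x) < 5:
        raise ValueError("profile needs at least 5 samples")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan"), 0.0, False

    def model(xv, amp, mu, sigma, offset):
        return amp * np.exp(-((xv - mu) ** 2) / (2 * sigma**2)) + offset

    span = x.max() - x.min()
    p0 = (max(y.max() - y.min(), 1e-12), float(x[np.argmax(y)]), span / 6, float(y.min()))
    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=p0,
            bounds=([0.0, x.min() - span, 1e-3, -np.inf], [np.inf, x.max() + span, 10 * span, np.inf]),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return float("nan"), 0.0, False
    resid = y - model(x, *popt)
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    sigma = abs(float(popt[2]))
    return sigma, r2, r2 > r2_min


def measure_sizes(
    channels,
    spots,
    half_length_px: int = 7,
    r2_min: float = 0.75,
) -> list[SizeMeasurement]:
    """Size every localized spot in every channel from its x line profile."""
    out = []
    for s in spots:
        for c, grid in enumerate(channels):
            x_nm, prof = line_profile(grid, s.positions_nm[c], half_length_px)
            if len(x_nm) < 5:
                continue
            sigma, r2, ok = fit_profile(x_nm, prof, r2_min)
            out.append(
                SizeMeasurement(
                    vesicle_id=s.vesicle_id,
                    channel_name=grid.channel_name,
                    sigma_nm=sigma,
                    r_squared=r2,
                    accepted=ok,
                )
            )
    return out


def size_distribution(
    measurements: Sequence[SizeMeasurement],
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Median sigma and FWHM of accepted fits with bootstrap 95% CIs.

    The CI of the median comes from a seeded percentile bootstrap.  With no
    accepted measurement every statistic is NaN.
    """
    sigmas = np.array([m.sigma_nm for m in measurements if m.accepted])
    n_rejected = sum(not m.accepted for m in measurements)
    if len(sigmas) == 0:
        nan = float("nan")
        return {
            "n_accepted": 0,
            "n_rejected": n_rejected,
            "median_sigma_nm": nan,
            "sigma_ci95_nm": (nan, nan),
            "median_fwhm_nm": nan,
            "fwhm_ci95_nm": (nan, nan),
        }
    rng = np.random.default_rng(seed)
    med = float(np.median(sigmas))
    boots = np.median(
        rng.choice(sigmas, size=(n_boot, len(sigmas)), replace=True), axis=1
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "n_accepted": int(len(sigmas)),
        "n_rejected": int(n_rejected),
        "median_sigma_nm": med,
        "sigma_ci95_nm": (float(lo), float(hi)),
        "median_fwhm_nm": FWHM_FACTOR * med,
        "fwhm_ci95_nm": (FWHM_FACTOR * float(lo), FWHM_FACTOR * float(hi)),
    }
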