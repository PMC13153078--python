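"""Spectral preprocessing: ROI averaging, Gaussian denoising, band lookup."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ricelpn.synth import ParameterError, Spectrum


class EmptyRoiError(ValueError):
    """ROI contains no pixels."""


class GridMismatchError(ValueError):
    """Spectra do not share one wavelength grid."""


class OutOfRangeError(ValueError):
    """Requested wavelength is outside the sensor range."""


@dataclass(frozen=True)
class RoiPixelSet:
    """Per-plot region of interest: pixel spectra on one wavelength grid."""

    pixels: list[Spectrum]
    plot_id: str = ""


def roi_mean(roi: RoiPixelSet) -> Spectrum:
    """Per-band arithmetic mean spectrum over all ROI pixels."""
    if not roi.pixels:
        raise EmptyRoiError(f"ROI {roi.plot_id!r} has no pixels")
    wl = roi.pixels[0].wavelengths
    for p in roi.pixels[1:]:
        if p.wavelengths.shape != wl.shape or not np.array_equal(p.wavelengths, wl):
            raise GridMismatchError(f"ROI {roi.plot_id!r}: pixel wavelength grids differ")
    mean_r = np.mean([p.reflectance for p in roi.pixels], axis=0)
    return Spectrum(wavelengths=wl, reflectance=mean_r)


def gaussian_smooth(s: Spectrum, sigma_bands: float = 1.0) -> Spectrum:
    """Gaussian denoising along the band axis.

    Discrete Gaussian kernel truncated at 4 sigma, unit-normalized,
    reflect-padded edges.  sigma_bands is in band units (not nm);
    sigma_bands = 0 returns the input unchanged.
    """
    if sigma_bands < 0:
        raise ParameterError(f"sigma_bands must be nonnegative, got {sigma_bands}")
    if sigma_bands == 0:
        return s
    smoothed = gaussian_filter1d(s.reflectance, sigma=sigma_bands, mode="reflect", truncate=4.0)
    return Spectrum(wavelengths=s.wavelengths, reflectance=np.clip(smoothed, 0.0, 1.0))


def nearest_band(s: Spectrum, target_nm: float) -> tuple[int, float]:
    """Resolve a nominal wavelength to the closest band center.

    Returns (band index, actual center wavelength).  Exact ties go to the
    lower wavelength.  Targets more than one band spacing outside the grid
    raise OutOfRangeError.
    """
    wl = s.wavelengths
    spacing = float(wl[1] - wl[0]) if wl.size >= 2 else 0.0
    if target_nm < wl[0] - spacing or target_nm > wl[-1] + spacing:
        raise OutOfRangeError(
            f"target {target_nm} nm outside [{wl[0] - spacing}, {wl[-1] + spacing}]"
        )
    idx = int(np.argmin(np.abs(wl - target_nm)))  # argmin takes the first ⇒ lower-λ tie rule
    return idx, float(wl[idx])
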