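"""High-pass spatial filtering of stiffness stacks.

Structures larger than a cutoff scale (default 1.5 cm) are suppressed to
emphasize mass-scale stiffness against broad parenchymal regions.  The
default kernel is Gaussian subtraction, ``F = S - G_sigma(S)``, with the
Gaussian FWHM equal to the cutoff scale; a Fourier-domain Butterworth
high-pass is available as an alternative.  Filtering is 2-D, per coronal
slice: review is slice-based and the out-of-plane spacing is coarse.

After filtering, the map is re-stretched per breast to [0, 1] (robust
percentiles) so that the three-class stiffness split and mass indices stay
on the same scale as the unfiltered map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .fusion import robust_normalize
from .stacks import ImageStack

#: FWHM = _FWHM_SIGMA * sigma for a Gaussian.
_FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class FilterParams:
    cutoff_scale: float = 15.0  # mm; spatial scales above this are suppressed
    kernel: str = "gaussian_subtraction"  # or "fourier_butterworth"
    renormalize: bool = True
    butterworth_order: int = 2

    def __post_init__(self):
        if self.cutoff_scale <= 0:
            raise ValueError("cutoff_scale must be positive")
        if self.kernel not in ("gaussian_subtraction", "fourier_butterworth"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


def highpass_slice(slice2d, spacing_xy, params: FilterParams | None = None) -> np.ndarray:
    """High-pass filter one coronal slice.

    Gaussian subtraction removes the DC component exactly (a constant slice
    maps to zero) and is linear in the input.
    """
    params = params or FilterParams()
    slice2d = np.asarray(slice2d, dtype=float)
    if slice2d.ndim != 2:
        raise ValueError("highpass_slice expects a 2-D slice")
    dx, dy = float(spacing_xy[0]), float(spacing_xy[1])
    if params.cutoff_scale < 2.0 * max(dx, dy):
        raise ValueError(
            f"cutoff_scale {params.cutoff_scale} mm is below two pixels at "
            f"spacing {spacing_xy}"
        )
    if params.kernel == "gaussian_subtraction":
        sigma_mm = params.cutoff_scale / _FWHM_SIGMA
        return slice2d - gaussian_filter(slice2d, sigma=(sigma_mm / dx, sigma_mm / dy))
    return _butterworth_highpass(slice2d, (dx, dy), params.cutoff_scale, params.butterworth_order)


def _butterworth_highpass(slice2d, spacing_xy, cutoff_mm, order) -> np.ndarray:
    """Fourier-domain Butterworth high-pass (cutoff at spatial scale in mm)."""
    nx, ny = slice2d.shape
    fx = np.fft.fftfreq(nx, d=spacing_xy[0])
    fy = np.fft.fftfreq(ny, d=spacing_xy[1])
    f = np.sqrt(fx[:, None] ** 2 + fy[None, :] ** 2)
    fc = 1.0 / cutoff_mm
    with np.errstate(divide="ignore"):
        H = 1.0 / (1.0 + (fc / np.where(f > 0, f, np.inf)) ** (2 * order))
    H[0, 0] = 0.0
    return np.real(np.fft.ifft2(np.fft.fft2(slice2d) * H))


def gaussian_transfer(wavelength_mm: float, cutoff_mm: float = 15.0) -> float:
    """Analytic attenuation of a sinusoid by the Gaussian-subtraction filter.

    Transfer = 1 - exp(-2 pi^2 sigma^2 / lambda^2), with sigma = FWHM/2.3548.
    """
    sigma = cutoff_mm / _FWHM_SIGMA
    return 1.0 - float(np.exp(-2.0 * np.pi**2 * sigma**2 / wavelength_mm**2))


def apply_highpass_stack(S: ImageStack, breast_mask, params: FilterParams | None = None) -> ImageStack:
    """High-pass every coronal slice of a stiffness stack.

    With ``renormalize`` (default) the result is robustly re-stretched to
    [0, 1] per breast so downstream three-class K-means and mass stiffness
    indices remain on the unit scale; otherwise negative values are clipped.
    """
    params = params or FilterParams()
    mask3d = (breast_mask.data if isinstance(breast_mask, ImageStack) else np.asarray(breast_mask)).astype(bool)
    if not mask3d.any():
        raise ValueError("mask is empty")
    out = np.empty_like(np.asarray(S.data, dtype=float))
    for k in range(S.shape[2]):
        out[:, :, k] = highpass_slice(S.data[:, :, k], S.spacing[:2], params)
    filtered = S.like(out, modality="stiffness", units="")
    if params.renormalize:
        return robust_normalize(filtered, mask3d)
    clipped = np.clip(out, 0.0, 1.0)
    clipped[~mask3d] = 0.0
    return S.like(clipped, modality="stiffness", units="")
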