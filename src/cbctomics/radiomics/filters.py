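"""Derived images for feature extraction: intensity transforms, gradient,
Laplacian of Gaussian and single-level 3D wavelet sub-bands.

Intensity transforms (square, square root, logarithm, exponential) act on the
volume rescaled to [0, 1] by its own range and are mapped back to the
original intensity span, so the same fixed-bin-width discretization applies
to every image type.  The gradient image is the spacing-aware gradient
magnitude in intensity units per mm.  LoG images are scale-normalised
(multiplied by sigma^2) so responses are comparable across sigma.  Wavelet
sub-bands come from a single-level stationary (undecimated) separable
decomposition; sub-band names spell the low/high-pass choice per axis in
(x, y, z) order, so ``HLH`` is high-pass in x, low-pass in y, high-pass in z.
"""
from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

__all__ = [
    "intensity_transforms",
    "gradient_magnitude",
    "log_filter",
    "wavelet_subbands",
    "TRANSFORM_NAMES",
]

TRANSFORM_NAMES = ("square", "squareroot", "logarithm", "exponential")


def _check_finite(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValueError("image contains non-finite values")
    return data


def intensity_transforms(data: np.ndarray) -> dict[str, np.ndarray]:
    """Monotone intensity remappings, rescaled back to the input span."""
    data = _check_finite(data)
    mn, mx = float(data.min()), float(data.max())
    span = mx - mn
    if span == 0:
        return {name: data.copy() for name in TRANSFORM_NAMES}
    u = (data - mn) / span
    out = {
        "square": u**2,
        "squareroot": np.sqrt(u),
        "logarithm": np.log1p(u) / np.log(2.0),
        "exponential": (np.exp(u) - 1.0) / (np.e - 1.0),
    }
    return {k: mn + v * span for k, v in out.items()}


def gradient_magnitude(data: np.ndarray, spacing) -> np.ndarray:
    """Euclidean norm of the spacing-aware intensity gradient (units/mm)."""
    data = _check_finite(data)
    gx, gy, gz = np.gradient(data, *spacing)
    return np.sqrt(gx**2 + gy**2 + gz**2)


def log_filter(data: np.ndarray, spacing, sigma_mm: float) -> np.ndarray:
    """Scale-normalised Laplacian of Gaussian at physical scale ``sigma_mm``.

    The Laplacian is assembled from per-axis second derivatives divided by
    the squared axis spacing, so the response is defined in physical (mm)
    units on anisotropic grids; the mean is subtracted first so a constant
    volume maps to (numerically) zero despite kernel truncation.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be > 0")
    data = _check_finite(data)
    centred = data - data.mean()
    sig_vox = [sigma_mm / s for s in spacing]
    out = np.zeros_like(centred)
    for ax, sp in enumerate(spacing):
        order = [0, 0, 0]
        order[ax] = 2
        out += ndimage.gaussian_filter(centred, sig_vox, order=order) / sp**2
    return sigma_mm**2 * out


def wavelet_subbands(data: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """8 same-shape sub-bands (LLL..HHH) of a single-level stationary 3D DWT."""
    data = _check_finite(data)
    shape = data.shape
    pad = [(0, n % 2) for n in shape]  # stationary transform needs even dims
    padded = np.pad(data, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out = {}
    for key, band in coeffs.items():
        name = "".join("L" if ch == "a" else "H" for ch in key)
        out[name] = band[: shape[0], : shape[1], : shape[2]]
    assert len(out) == 8
    return out
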