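"""FFT high-pass filtering and gradient magnitude of a thermal frame.

The high-pass stage removes the dominant low-frequency content of the raw
temperature grid so that the subsequent gradient image responds to leaf
edges rather than to the absolute temperature level. The filter zeroes every
Fourier coefficient whose magnitude is at least that of the DC (zero
frequency) coefficient — in natural thermal images the DC term dominates, so
in practice this removes DC (the image mean) and nothing else.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .io import MIN_SIDE, ThermalFrame

__all__ = ["highpass_fft", "gradient_magnitude"]


def highpass_fft(frame: ThermalFrame | np.ndarray) -> np.ndarray:
    """High-pass filter a thermal frame in the Fourier domain.

    The 2D FFT is taken, coefficients with magnitude >= the DC magnitude are
    zeroed (always including DC itself), and the real part of the inverse
    transform is returned. The output has the source shape and, when only DC
    is removed, zero mean to numerical precision.
    """
    values = frame.values if isinstance(frame, ThermalFrame) else np.asarray(frame, float)
    h, w = values.shape
    if h < MIN_SIDE or w < MIN_SIDE:
        raise ValueError(f"frame {h}x{w} below minimum {MIN_SIDE}x{MIN_SIDE} for FFT")
    spectrum = sp_fft.fft2(values)
    mags = np.abs(spectrum)
    dc_mag = mags[0, 0]
    # An (already filtered) zero-mean image has no continuous component to
    # remove; treating a numerically-zero DC as a threshold would wipe the
    # whole spectrum, so the filter is the identity there. This makes the
    # operation idempotent.
    if dc_mag <= 1e-12 * max(mags.max(), 1.0):
        return values.astype(float, copy=True)
    keep = mags < dc_mag  # zeroes DC and any coefficient >= |DC|
    filtered = sp_fft.ifft2(spectrum * keep).real
    return filtered


def gradient_magnitude(filtered: np.ndarray, operator: str = "sobel") -> np.ndarray:
    """Per-pixel gradient magnitude sqrt(gx² + gy²) of a filtered image.

    ``operator`` is ``"sobel"`` (3×3, the default of the image-processing
    ecosystem this pipeline targets) or ``"central"`` (first-order central
    differences). Borders are handled by edge replication.
    """
    img = np.asarray(filtered, dtype=float)
    if operator == "sobel":
        gy = ndimage.sobel(img, axis=0, mode="nearest")
        gx = ndimage.sobel(img, axis=1, mode="nearest")
    elif operator == "central":
        gy, gx = np.gradient(img, edge_order=1)
    else:
        raise ValueError(f"unknown gradient operator {operator!r}")
    return np.hypot(gx, gy)
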