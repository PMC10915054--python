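"""Leaf-mask segmentation from the gradient of the high-pass-filtered frame.

The segmentation is fully non-parametric in the sense that its threshold is
derived from the gradient image itself: the first and third quartiles q1, q3
of the gradient values give the interquartile range IQR = q3 − q1 and the
Tukey fences

    thr_dw = q1 − multiplier·IQR        thr_up = q3 + multiplier·IQR

(multiplier 1.5 by default). Pixels whose gradient magnitude falls outside
the fences — in practice the strong leaf-edge responses above thr_up, since
gradient magnitudes are non-negative and thr_dw is usually negative — seed
the binary mask, which is then dilated, hole-filled, eroded, and reduced to
its largest connected component. A ``low_only`` binarization mode keeps only
the lower-fence test for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .io import ThermalFrame
from .preprocess import gradient_magnitude, highpass_fft

__all__ = [
    "FenceSpec",
    "SegmentationConfig",
    "SegmentationError",
    "compute_fences",
    "binarize_gradient",
    "refine_mask",
    "segment_leaf",
    "mask_iou",
]


class SegmentationError(RuntimeError):
    """Segmentation produced no usable leaf component.

    Carries diagnostics: the raw on-pixel count and the component sizes seen
    before the failure, so callers can log why a frame was discarded.
    """

    def __init__(self, message: str, raw_on_pixels: int = 0, component_sizes=()):
        super().__init__(message)
        self.raw_on_pixels = int(raw_on_pixels)
        self.component_sizes = list(component_sizes)


@dataclass(frozen=True)
class FenceSpec:
    """Quartile fences of a gradient image (Tukey outlier rule)."""

    q1: float
    q3: float
    multiplier: float = 1.5

    def __post_init__(self) -> None:
        if self.q3 < self.q1:
            raise ValueError(f"q3={self.q3} < q1={self.q1}")

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def thr_dw(self) -> float:
        return self.q1 - self.multiplier * self.iqr

    @property
    def thr_up(self) -> float:
        return self.q3 + self.multiplier * self.iqr


def compute_fences(gradient: np.ndarray, multiplier: float = 1.5) -> FenceSpec:
    """Quartiles (linear interpolation, type-7) over all gradient pixels."""
    g = np.asarray(gradient, dtype=float)
    if g.size == 0:
        raise ValueError("empty gradient image")
    q1, q3 = np.quantile(g, [0.25, 0.75])  # numpy default = linear / type-7
    return FenceSpec(q1=float(q1), q3=float(q3), multiplier=multiplier)


def binarize_gradient(
    gradient: np.ndarray, fences: FenceSpec, mode: str = "two_sided"
) -> np.ndarray:
    """Binary mask of gradient pixels outside the quartile fences.

    ``two_sided`` (default): on where δ < thr_dw or δ > thr_up.
    ``low_only``: on where δ < thr_dw only — usually vacuous for
    non-negative gradient magnitudes, retained for comparison.
    """
    g = np.asarray(gradient, dtype=float)
    if mode == "two_sided":
        return (g < fences.thr_dw) | (g > fences.thr_up)
    if mode == "low_only":
        return g < fences.thr_dw
    raise ValueError(f"unknown binarization mode {mode!r}")


def refine_mask(
    raw: np.ndarray,
    struct_radius: int = 3,
    connectivity: int = 8,
    min_area: int = 50,
) -> np.ndarray:
    """Dilate, fill holes, erode, then keep the largest connected component.

    The structuring element is a disk of ``struct_radius`` pixels for both
    the dilation and the erosion. Ties in component size break toward the
    smallest label (scan order). Raises :class:`SegmentationError` if the
    final component is empty or smaller than ``min_area`` pixels.
    """
    raw = np.asarray(raw, dtype=bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    n_raw = int(raw.sum())
    if n_raw == 0:
        raise SegmentationError("empty raw mask: no gradient outliers", 0, [])
    selem = morphology.disk(struct_radius).astype(bool)
    work = ndimage.binary_dilation(raw, structure=selem)
    work = ndimage.binary_fill_holes(work)
    work = ndimage.binary_erosion(work, structure=selem)
    labels = measure.label(work, connectivity=2 if connectivity == 8 else 1)
    if labels.max() == 0:
        raise SegmentationError(
            "mask vanished during morphological refinement", n_raw, []
        )
    sizes = np.bincount(labels.ravel())[1:]  # component 0 is background
    best = int(np.argmax(sizes)) + 1  # argmax takes the first (smallest label) tie
    if sizes[best - 1] < min_area:
        raise SegmentationError(
            f"largest component {sizes[best - 1]} px below min_area={min_area}",
            n_raw,
            sizes.tolist(),
        )
    return labels == best


@dataclass(frozen=True)
class SegmentationConfig:
    mode: str = "two_sided"
    multiplier: float = 1.5
    struct_radius: int = 3
    connectivity: int = 8
    min_area: int = 50
    gradient_operator: str = "sobel"


def segment_leaf(
    frame: ThermalFrame, config: SegmentationConfig = SegmentationConfig()
) -> np.ndarray:
    """Full deterministic segmentation chain for one thermal frame.

    highpass_fft → gradient_magnitude → compute_fences → binarize_gradient
    → refine_mask. There is no randomness anywhere in the chain; identical
    frames give identical masks.
    """
    filtered = highpass_fft(frame)
    grad = gradient_magnitude(filtered, operator=config.gradient_operator)
    fences = compute_fences(grad, multiplier=config.multiplier)
    raw = binarize_gradient(grad, fences, mode=config.mode)
    return refine_mask(
        raw,
        struct_radius=config.struct_radius,
        connectivity=config.connectivity,
        min_area=config.min_area,
    )


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
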