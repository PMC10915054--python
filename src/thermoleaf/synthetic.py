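"""Synthetic thermal leaf scenes with known ground truth.

Emulates the imaging setup of a handheld thermal camera pointed at a single
leaf held against a white paper backdrop: a warm or cool leaf-shaped region
over a flat background, a smooth within-leaf temperature gradient, optics
blur, and additive sensor noise. Dry-down (DD) leaves are generated warmer
than well-watered (WW) leaves because stomatal closure reduces evaporative
cooling; the offset magnitude is configurable.

Every scene carries its pre-blur ground-truth mask, so segmentation and
feature extraction can be scored without any real imagery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import ThermalFrame

__all__ = [
    "LeafSceneSpec",
    "SyntheticSample",
    "generate_leaf_scene",
    "generate_cohort",
]

GEOMETRIES = ("ellipse", "lobed", "okra")


class SceneSpecError(ValueError):
    """Scene specification violates its contract (geometry or area bounds)."""


@dataclass(frozen=True)
class LeafSceneSpec:
    """Parameters of one synthetic leaf-on-backdrop thermal scene.

    Temperatures are °C; sizes in pixels. ``axes`` are the semi-axes of the
    base ellipse; lobed and okra leaves are unions of rotated ellipses built
    on the same base (no botanical fidelity claimed — they exist to exercise
    mask topology).
    """

    shape: tuple[int, int] = (120, 160)
    background_temp: float = 22.0
    leaf_temp_mean: float = 27.0
    leaf_temp_sd: float = 0.3
    noise_sd: float = 0.15
    blur_sigma: float = 1.0
    leaf_geometry: str = "ellipse"
    axes: tuple[float, float] = (35.0, 25.0)
    rotation_deg: float = 0.0
    center: tuple[float, float] | None = None  # defaults to frame centre
    gradient_amplitude: float = 0.5  # smooth within-leaf trend, °C tip-to-base
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leaf_geometry not in GEOMETRIES:
            raise SceneSpecError(
                f"unknown leaf_geometry {self.leaf_geometry!r}; "
                f"expected one of {GEOMETRIES}"
            )
        if self.noise_sd < 0 or self.blur_sigma < 0 or self.leaf_temp_sd < 0:
            raise SceneSpecError("noise_sd, blur_sigma, leaf_temp_sd must be >= 0")
        if min(self.shape) < 8:
            raise SceneSpecError(f"frame {self.shape} too small")


@dataclass
class SyntheticSample:
    """A generated frame, its ground-truth leaf mask, and the treatment label."""

    frame: ThermalFrame
    truth_mask: np.ndarray  # bool, pre-blur leaf support
    treatment: str  # "WW" or "DD"


def _ellipse_support(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    rotation_deg: float,
) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = center
    th = math.radians(rotation_deg)
    dy, dx = yy - cy, xx - cx
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _leaf_support(spec: LeafSceneSpec) -> np.ndarray:
    h, w = spec.shape
    center = spec.center if spec.center is not None else (h / 2.0, w / 2.0)
    a, b = spec.axes
    if spec.leaf_geometry == "ellipse":
        return _ellipse_support(spec.shape, center, (a, b), spec.rotation_deg)
    # lobed / okra: union of rotated ellipses sharing the centre; okra lobes
    # are narrower and longer (deep sinuses), lobed ones broad (shallow)
    if spec.leaf_geometry == "lobed":
        lobes, la, lb = 3, a, 0.55 * b
    else:  # okra
        lobes, la, lb = 5, a, 0.30 * b
    support = np.zeros(spec.shape, dtype=bool)
    for k in range(lobes):
        ang = spec.rotation_deg + 180.0 * k / lobes
        support |= _ellipse_support(spec.shape, center, (la, lb), ang)
    return support


def generate_leaf_scene(spec: LeafSceneSpec) -> SyntheticSample:
    """Render one scene. Deterministic for a fixed ``spec`` (incl. seed).

    The leaf pixels are drawn i.i.d. around ``leaf_temp_mean`` with
    ``leaf_temp_sd``, plus a smooth linear trend of ``gradient_amplitude``
    across the leaf. The whole frame is then Gaussian-blurred
    (``blur_sigma``) and sensor noise (``noise_sd``) added. The returned
    ``truth_mask`` is the pre-blur leaf support.

    Raises :class:`SceneSpecError` if the leaf would exceed the frame bounds
    or its area falls outside 5–70 % of the frame.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    support = _leaf_support(spec)
    # leaf must fit strictly inside the frame
    border = np.concatenate(
        [support[0, :], support[-1, :], support[:, 0], support[:, -1]]
    )
    if border.any():
        raise SceneSpecError("leaf geometry touches or exceeds the frame bounds")
    frac = support.mean()
    if not (0.05 <= frac <= 0.70):
        raise SceneSpecError(
            f"leaf area fraction {frac:.3f} outside the allowed [0.05, 0.70]"
        )

    img = np.full((h, w), spec.background_temp, dtype=float)
    n_leaf = int(support.sum())
    leaf_vals = spec.leaf_temp_mean + spec.leaf_temp_sd * rng.standard_normal(n_leaf)
    img[support] = leaf_vals
    if spec.gradient_amplitude != 0.0:
        rows = np.nonzero(support)[0]
        rmin, rmax = rows.min(), rows.max()
        span = max(rmax - rmin, 1)
        trend = (np.arange(h) - rmin) / span - 0.5
        img[support] += spec.gradient_amplitude * trend[np.nonzero(support)[0]]
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="nearest")
    if spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal((h, w))

    frame = ThermalFrame(img, sample_id=f"scene_{spec.seed}")
    return SyntheticSample(frame=frame, truth_mask=support, treatment="unknown")


DEFAULT_DD_OFFSET = 2.0  # °C of stomatal-closure warming under dry-down


def generate_cohort(
    n_per_class: int,
    ww_params: LeafSceneSpec = LeafSceneSpec(),
    dd_offset: float = DEFAULT_DD_OFFSET,
    seed: int = 0,
    geometry_jitter: bool = True,
) -> list[SyntheticSample]:
    """Generate a balanced cohort of 2·``n_per_class`` labeled scenes.

    DD leaves are drawn with a mean temperature ``dd_offset`` °C above the WW
    template. Per-sample leaf size, rotation, centre and mean temperature are
    jittered to mimic genotype diversity; all randomness derives from
    ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    samples: list[SyntheticSample] = []
    for label, offset in (("WW", 0.0), ("DD", dd_offset)):
        for i in range(n_per_class):
            sub = int(rng.integers(0, 2**31 - 1))
            spec = replace(ww_params, seed=sub)
            if geometry_jitter:
                scale = float(rng.uniform(0.75, 1.1))
                h, w = spec.shape
                spec = replace(
                    spec,
                    axes=(spec.axes[0] * scale, spec.axes[1] * scale),
                    rotation_deg=float(rng.uniform(0, 180)),
                    center=(
                        h / 2.0 + float(rng.uniform(-0.05, 0.05)) * h,
                        w / 2.0 + float(rng.uniform(-0.05, 0.05)) * w,
                    ),
                    leaf_geometry=str(rng.choice(GEOMETRIES)),
                )
            spec = replace(
                spec,
                leaf_temp_mean=spec.leaf_temp_mean
                + offset
                + float(rng.normal(0, 0.4)),  # genotype-to-genotype spread
            )
            sample = generate_leaf_scene(spec)
            sample.treatment = label
            sample.frame.sample_id = f"{label.lower()}_{i:04d}"
            sample.frame.metadata["treatment"] = label
            samples.append(sample)
    return samples
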