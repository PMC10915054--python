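"""Statistical thermal indicators of a masked leaf.

Masked temperatures are first passed through a single Tukey-fence outlier
filter (the same 1.5·IQR device used for segmentation), which makes the
indicators robust to small leaf-mask misalignments: a thin ring of backdrop
pixels leaking into the mask lands outside the fences of the leaf
temperature distribution and is discarded. The nine indicators are then
computed on the filtered values: mean, standard deviation (sample, n−1, by
default), median, 25th and 75th percentiles, interquartile range, max, min,
and temperature range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ThermalFrame

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "InsufficientDataError",
    "filter_outliers",
    "extract_features",
    "features_to_frame",
]

FEATURE_NAMES = ["mean", "std", "median", "p25", "p75", "iqr", "max", "min", "range"]


class InsufficientDataError(ValueError):
    """Too few pixels/values to compute robust thermal indicators."""


@dataclass(frozen=True)
class FeatureVector:
    """The statistical thermal indicators (°C) of one masked leaf."""

    mean: float
    std: float
    median: float
    p25: float
    p75: float
    iqr: float
    max: float
    min: float
    range: float
    n_pixels_used: int
    n_outliers_removed: int

    def __post_init__(self) -> None:
        # order invariants of any sane temperature summary
        assert self.min <= self.p25 <= self.median <= self.p75 <= self.max
        assert abs(self.iqr - (self.p75 - self.p25)) < 1e-9
        assert abs(self.range - (self.max - self.min)) < 1e-9
        assert self.std >= 0

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES} | {
            "n_pixels_used": self.n_pixels_used,
            "n_outliers_removed": self.n_outliers_removed,
        }


def filter_outliers(temps, multiplier: float = 1.5) -> np.ndarray:
    """Single-pass Tukey-fence outlier removal.

    Values strictly outside [q1 − m·IQR, q3 + m·IQR] of the *input* sample
    are dropped; values equal to a fence are retained. Fences are computed
    once (no iteration). Requires at least 4 values.
    """
    t = np.asarray(temps, dtype=float).ravel()
    if t.size < 4:
        raise InsufficientDataError(
            f"need >= 4 values for quartile fences, got {t.size}"
        )
    q1, q3 = np.quantile(t, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    return t[(t >= lo) & (t <= hi)]


def extract_features(
    frame: ThermalFrame,
    mask: np.ndarray,
    multiplier: float = 1.5,
    min_pixels: int = 10,
    std_ddof: int = 1,
) -> FeatureVector:
    """Compute the nine thermal indicators of the masked, outlier-filtered
    temperatures.

    Raises :class:`InsufficientDataError` if fewer than ``min_pixels``
    temperatures survive the outlier filter. Quantiles use linear (type-7)
    interpolation, matching the segmentation stage.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != frame.values.shape:
        raise ValueError(
            f"mask shape {mask.shape} != frame shape {frame.values.shape}"
        )
    temps = frame.values[mask]
    kept = filter_outliers(temps, multiplier=multiplier)
    if kept.size < min_pixels:
        raise InsufficientDataError(
            f"{kept.size} pixels after outlier filtering "
            f"(from {temps.size} masked) below floor {min_pixels}"
        )
    p25, med, p75 = np.quantile(kept, [0.25, 0.5, 0.75])
    vmin, vmax = float(kept.min()), float(kept.max())
    return FeatureVector(
        mean=float(kept.mean()),
        std=float(kept.std(ddof=std_ddof)),
        median=float(med),
        p25=float(p25),
        p75=float(p75),
        iqr=float(p75 - p25),
        max=vmax,
        min=vmin,
        range=vmax - vmin,
        n_pixels_used=int(kept.size),
        n_outliers_removed=int(temps.size - kept.size),
    )


def features_to_frame(rows: list[tuple[ThermalFrame, FeatureVector]]) -> pd.DataFrame:
    """Assemble per-sample feature vectors into the tabular feature table.

    Columns: sample_id, genotype, treatment, timepoint, drought_stage, the
    nine indicators, and the pixel bookkeeping counts.
    """
    records = []
    for frame, fv in rows:
        rec = {
            "sample_id": frame.sample_id,
            "genotype": frame.metadata.get("genotype", "unknown"),
            "treatment": frame.metadata.get("treatment", "unknown"),
            "timepoint": frame.metadata.get("timepoint", "unknown"),
            "drought_stage": frame.metadata.get("drought_stage", "unknown"),
        }
        rec.update(fv.as_dict())
        records.append(rec)
    return pd.DataFrame.from_records(records)
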