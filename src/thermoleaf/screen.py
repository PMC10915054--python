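"""Kolmogorov–Smirnov feature screening between treatment groups.

Each thermal indicator is compared between the well-watered (WW) and
dry-down (DD) groups with a two-sample, two-sided KS test; features whose
p-value is below alpha are kept as discriminating, the rest are dropped
before classification. No multiple-testing correction is applied.

Screening runs on the full labeled dataset by default (feature removal
before the train/validation split); ``screen_after_split`` callers can
instead pass only the training rows for the leakage-free variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

__all__ = ["ScreenResult", "ks_two_sample", "screen_features", "kept_features"]


@dataclass(frozen=True)
class ScreenResult:
    feature_name: str
    ks_statistic: float
    p_value: float
    discriminating: bool
    n_ww: int
    n_dd: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        assert 0.0 <= self.ks_statistic <= 1.0
        assert 0.0 <= self.p_value <= 1.0
        assert self.discriminating == (self.p_value < self.alpha)


def ks_two_sample(a, b, method: str = "asymp") -> tuple[float, float]:
    """Two-sample two-sided KS test: statistic = sup |ECDF_a − ECDF_b|.

    ``method`` is passed to scipy (``asymp`` default; ``exact`` available
    for small samples). Each sample must contain at least 3 values.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError(f"samples too small for KS test: {a.size}, {b.size}")
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def screen_features(
    table: pd.DataFrame,
    alpha: float = 0.05,
    feature_names: list[str] | None = None,
    method: str = "asymp",
) -> list[ScreenResult]:
    """Screen every feature column of a feature table between WW and DD.

    ``table`` must carry a ``treatment`` column with both classes present.
    Results are ordered by ascending p-value.
    """
    feature_names = feature_names or FEATURE_NAMES
    groups = set(table["treatment"])
    if not {"WW", "DD"} <= groups:
        raise ValueError(
            f"both WW and DD must be present for screening; got {sorted(groups)}"
        )
    ww = table[table["treatment"] == "WW"]
    dd = table[table["treatment"] == "DD"]
    results = []
    for name in feature_names:
        stat, p = ks_two_sample(ww[name], dd[name], method=method)
        results.append(
            ScreenResult(
                feature_name=name,
                ks_statistic=stat,
                p_value=p,
                discriminating=p < alpha,
                n_ww=len(ww),
                n_dd=len(dd),
                alpha=alpha,
            )
        )
    return sorted(results, key=lambda r: r.p_value)


def kept_features(results: list[ScreenResult]) -> list[str]:
    """Names of the discriminating features, best p-value first."""
    return [r.feature_name for r in results if r.discriminating]


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_name": r.feature_name,
                "ks_statistic": r.ks_statistic,
                "p_value": r.p_value,
                "discriminating": r.discriminating,
                "n_ww": r.n_ww,
                "n_dd": r.n_dd,
                "alpha": r.alpha,
            }
            for r in results
        ]
    )
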