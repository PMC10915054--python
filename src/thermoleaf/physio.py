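"""Physiological plausibility check of classifier outcomes.

Joins per-sample classifier predictions with leaf-level physiology (soil
volumetric water content, PSII efficiency, leaf water potential) and flags
samples whose physiology is an outlier for their own treatment group — the
same 1.5·IQR quartile-fence rule used throughout the pipeline, applied per
treatment and per trait. The output is associational only: flag rates by
prediction-outcome tag (DD_DD, DD_WW, WW_DD, WW_WW), never a causal claim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PhysioRecord", "MislabelDiagnosis", "join_predictions_physio",
           "flag_physio_outliers"]

log = logging.getLogger(__name__)

PHYSIO_TRAITS = ["soil_vwc", "psii_eff", "leaf_wp"]


@dataclass(frozen=True)
class PhysioRecord:
    """One sample's physiology: soil VWC (%), PSII efficiency (Fv/Fm or
    Fv'/Fm', in [0, 1]), leaf water potential (MPa, ≤ 0)."""

    sample_id: str
    soil_vwc: float
    psii_eff: float
    leaf_wp: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.soil_vwc <= 100.0:
            raise ValueError(f"{self.sample_id}: soil_vwc {self.soil_vwc} outside [0, 100] %")
        if not 0.0 <= self.psii_eff <= 1.0:
            raise ValueError(f"{self.sample_id}: psii_eff {self.psii_eff} outside [0, 1]")
        if self.leaf_wp > 0:
            raise ValueError(f"{self.sample_id}: leaf_wp {self.leaf_wp} must be <= 0 MPa")


@dataclass(frozen=True)
class MislabelDiagnosis:
    sample_id: str
    true_label: str
    predicted_label: str
    outcome: str  # true_predicted tag: DD_DD, DD_WW, WW_DD, WW_WW
    physio_outlier: bool
    which_traits: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.outcome == f"{self.true_label}_{self.predicted_label}"
        if self.physio_outlier:
            assert self.which_traits, "outlier flag requires at least one trait"


def join_predictions_physio(
    predictions: pd.DataFrame, physio: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join predictions (sample_id, true_label, predicted_label) with
    the physiology table on sample_id; unmatched ids are logged.

    Raises on duplicated physiology ids or an empty join.
    """
    dup = physio["sample_id"][physio["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicated physio sample_id values: {dup}")
    joined = predictions.merge(physio, on="sample_id", how="inner")
    unmatched = sorted(set(predictions["sample_id"]) - set(joined["sample_id"]))
    if unmatched:
        log.warning("%d predictions without physiology rows: %s",
                    len(unmatched), unmatched[:10])
    if joined.empty:
        raise ValueError("join of predictions and physiology is empty")
    joined = joined.assign(
        outcome=joined["true_label"] + "_" + joined["predicted_label"]
    )
    return joined


def flag_physio_outliers(
    joined: pd.DataFrame,
    traits: list[str] | None = None,
    multiplier: float = 1.5,
    min_group: int = 4,
) -> list[MislabelDiagnosis]:
    """Flag samples whose trait value lies outside the quartile fences of
    their own treatment group.

    Fences are q1 − m·IQR and q3 + m·IQR per (treatment, trait), computed on
    all rows of that treatment. A trait whose group has fewer than
    ``min_group`` rows is skipped with a warning.
    """
    traits = traits or PHYSIO_TRAITS
    fences: dict[tuple[str, str], tuple[float, float]] = {}
    for treatment, grp in joined.groupby("true_label"):
        for trait in traits:
            vals = grp[trait].to_numpy(float)
            if len(vals) < min_group:
                log.warning("group %s has %d rows; trait %s skipped",
                            treatment, len(vals), trait)
                continue
            q1, q3 = np.quantile(vals, [0.25, 0.75])
            iqr = q3 - q1
            fences[(treatment, trait)] = (q1 - multiplier * iqr, q3 + multiplier * iqr)

    diagnoses = []
    for row in joined.itertuples(index=False):
        flagged = []
        for trait in traits:
            key = (row.true_label, trait)
            if key not in fences:
                continue
            lo, hi = fences[key]
            v = float(getattr(row, trait))
            if v < lo or v > hi:
                flagged.append(trait)
        diagnoses.append(
            MislabelDiagnosis(
                sample_id=row.sample_id,
                true_label=row.true_label,
                predicted_label=row.predicted_label,
                outcome=row.outcome,
                physio_outlier=bool(flagged),
                which_traits=tuple(flagged),
            )
        )
    return diagnoses


def diagnosis_to_frame(diagnoses: list[MislabelDiagnosis]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "true_label": d.true_label,
                "predicted_label": d.predicted_label,
                "outcome": d.outcome,
                "physio_outlier": d.physio_outlier,
                "which_traits": ";".join(d.which_traits),
            }
            for d in diagnoses
        ]
    )


def flag_rates_by_outcome(diagnoses: list[MislabelDiagnosis]) -> pd.DataFrame:
    """Fraction of physiology-outlier samples per prediction-outcome tag."""
    df = diagnosis_to_frame(diagnoses)
    return (
        df.groupby("outcome")["physio_outlier"]
        .agg(["mean", "sum", "count"])
        .rename(columns={"mean": "flag_rate", "sum": "n_flagged", "count": "n"})
        .reset_index()
    )
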