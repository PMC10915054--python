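"""Random-forest and multilayer-perceptron drought classification pipelines.

Both pipelines share the same scaffold: a stratified 75/25 split into a
training/test subset T and a held-out validation subset V, per-feature
standardization to N(0, 1), mutual-information selection of the K most
label-informative features, randomized hyperparameter search with stratified
10-fold cross-validation on T, and a final classification report (per-class
precision/recall/F1/support, confusion matrix, overall accuracy) on V.

Default hyperparameters are the selected values of the reference setup: the
RF pipeline keeps K=3 features and uses trees with max depth 5 and a minimum
of 5 samples per leaf; the MLP pipeline keeps K=7 features and uses a single
hidden layer of 50 neurons trained with the Adam solver under a constant
learning-rate schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import partial

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectKBest, mutual_info_classif
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import (
    RandomizedSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SplitSpec",
    "PipelineConfig",
    "EvalReport",
    "ScaleParams",
    "split_dataset",
    "standardize",
    "select_features_mi",
    "tune_and_train",
    "evaluate",
    "compare_models",
]

CLASS_ORDER = ["DD", "WW"]  # row/column order of confusion matrices


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split: |T| = floor(train_fraction · N)."""

    train_fraction: float = 0.75
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_dataset(labels, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices into (T, V) index arrays, deterministic per seed.

    ``labels`` is the per-sample class label array (used for stratification
    and to determine N). |T| = floor(train_fraction·N), |V| = N − |T|; the
    two sets are disjoint and exhaustive.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 4:
        raise ValueError(f"need at least 4 samples to split, got {n}")
    n_train = int(np.floor(spec.train_fraction * n))
    idx = np.arange(n)
    try:
        train_idx, val_idx = train_test_split(
            idx,
            train_size=n_train,
            random_state=spec.seed,
            shuffle=True,
            stratify=labels if spec.stratified else None,
        )
    except ValueError as exc:
        raise ValueError(
            f"stratified {spec.train_fraction:.0%} split impossible for "
            f"n={n}: {exc}"
        ) from exc
    return np.sort(train_idx), np.sort(val_idx)


@dataclass(frozen=True)
class ScaleParams:
    """Per-feature location/scale fitted on training rows only."""

    mean: np.ndarray
    sd: np.ndarray
    constant_columns: tuple[int, ...] = ()


def standardize(
    train: np.ndarray, apply_to: np.ndarray | None = None, ddof: int = 1
) -> tuple[np.ndarray, np.ndarray | None, ScaleParams]:
    """Scale each feature to zero mean and unit sd using training statistics.

    Validation/extra rows (``apply_to``) are transformed with the training
    parameters. A zero-variance training column cannot be scaled: it is
    passed through centered (zeros) with a warning, and its index recorded.
    """
    train = np.asarray(train, dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=ddof)
    constant = tuple(int(j) for j in np.nonzero(sd == 0)[0])
    if constant:
        warnings.warn(
            f"zero-variance training columns {constant}: centered only",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    out_train = (train - mean) / safe_sd
    out_apply = None
    if apply_to is not None:
        out_apply = (np.asarray(apply_to, float) - mean) / safe_sd
    return out_train, out_apply, ScaleParams(mean=mean, sd=sd, constant_columns=constant)


def select_features_mi(
    train: pd.DataFrame, labels, k: int, seed: int = 0
) -> list[str]:
    """The k feature names with highest estimated mutual information with
    the class label; estimator seeded, fitted on training rows only."""
    if k > train.shape[1]:
        raise ValueError(f"k={k} exceeds {train.shape[1]} available features")
    mi = mutual_info_classif(
        np.asarray(train, float), np.asarray(labels), random_state=seed
    )
    order = np.argsort(-mi, kind="stable")[:k]  # stable: ties by column order
    return [train.columns[j] for j in sorted(order)]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one classification pipeline (``rf`` or ``mlp``).

    The random-search space is centred on the defaults; collapsing every
    dimension to a single value makes the search degenerate and returns the
    defaults unchanged.
    """

    model: str = "rf"
    k_features: int | None = None  # default: 3 for rf, 7 for mlp
    rf_n_estimators: int = 100
    rf_min_samples_leaf: int = 5
    rf_max_depth: int = 5
    mlp_hidden_size: int = 50
    mlp_alpha: float = 1e-4
    mlp_learning_rate_init: float = 1e-3
    mlp_max_iter: int = 500
    cv_folds: int = 10
    search_iterations: int = 25
    seed: int = 0
    search_space: dict | None = None  # None → default grid around Table values

    def __post_init__(self) -> None:
        if self.model not in ("rf", "mlp"):
            raise ValueError(f"model must be 'rf' or 'mlp', got {self.model!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def k(self) -> int:
        if self.k_features is not None:
            return self.k_features
        return 3 if self.model == "rf" else 7


def _default_search_space(config: PipelineConfig, n_features: int) -> dict:
    ks = [k for k in (3, 5, 7, 9) if k <= n_features] or [n_features]
    space: dict = {"select__k": ks}
    if config.model == "rf":
        space.update(
            {
                "model__max_depth": [3, 5, 7, 10],
                "model__min_samples_leaf": [2, 5, 10],
                "model__n_estimators": [100, 300],
            }
        )
    else:
        space.update(
            {
                "model__hidden_layer_sizes": [(25,), (50,), (100,)],
                "model__alpha": [1e-4, 1e-3],
                "model__learning_rate_init": [1e-3, 1e-2],
            }
        )
    return space


def build_pipeline(config: PipelineConfig, n_features: int) -> Pipeline:
    """Assemble scaler → MI feature selection → classifier."""
    k = min(config.k, n_features)
    if config.model == "rf":
        model = RandomForestClassifier(
            n_estimators=config.rf_n_estimators,
            max_depth=config.rf_max_depth,
            min_samples_leaf=config.rf_min_samples_leaf,
            random_state=config.seed,
        )
    else:
        model = MLPClassifier(
            hidden_layer_sizes=(config.mlp_hidden_size,),
            solver="adam",
            learning_rate="constant",
            learning_rate_init=config.mlp_learning_rate_init,
            alpha=config.mlp_alpha,
            max_iter=config.mlp_max_iter,
            early_stopping=False,
            random_state=config.seed,
        )
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "select",
                SelectKBest(
                    partial(mutual_info_classif, random_state=config.seed), k=k
                ),
            ),
            ("model", model),
        ]
    )


@dataclass
class TrainResult:
    pipeline: Pipeline  # best configuration refit on all of T
    best_params: dict
    cv_score: float
    feature_names: list[str]


def tune_and_train(
    X: pd.DataFrame, y, config: PipelineConfig
) -> TrainResult:
    """Randomized hyperparameter search with stratified k-fold CV on T.

    The best configuration is refit on all of T. Fully seeded: the search
    sampling, the CV folds, and every estimator derive from ``config.seed``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training subset must contain both classes")
    if len(y) < config.cv_folds:
        raise ValueError(
            f"n_T={len(y)} smaller than cv_folds={config.cv_folds}"
        )
    space = (
        config.search_space
        if config.search_space is not None
        else _default_search_space(config, X.shape[1])
    )
    n_points = int(np.prod([len(v) for v in space.values()])) if space else 1
    pipeline = build_pipeline(config, X.shape[1])
    cv = StratifiedKFold(config.cv_folds, shuffle=True, random_state=config.seed)
    search = RandomizedSearchCV(
        pipeline,
        space,
        n_iter=min(config.search_iterations, n_points),
        cv=cv,
        random_state=config.seed,
        scoring="accuracy",
        refit=True,
        error_score="raise",
    )
    with warnings.catch_warnings():
        # MLP fits inside the search may hit max_iter without full convergence
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        warnings.filterwarnings("ignore", category=UserWarning)
        search.fit(np.asarray(X, float), y)
    best = search.best_estimator_
    selected = [
        X.columns[j] for j in best.named_steps["select"].get_support(indices=True)
    ]
    return TrainResult(
        pipeline=best,
        best_params=dict(search.best_params_),
        cv_score=float(search.best_score_),
        feature_names=selected,
    )


@dataclass
class EvalReport:
    """Validation-set classification report.

    ``confusion`` rows are true classes, columns predicted, both in the
    order (DD, WW). Internal-consistency invariants (accuracy from the
    trace, F1 from precision/recall, support sums) are asserted on
    construction.
    """

    confusion: np.ndarray
    per_class: dict  # class -> {precision, recall, f1, support}
    accuracy: float
    n_validation: int
    model: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.confusion)
        assert c.shape == (2, 2)
        assert int(c.sum()) == self.n_validation
        assert int(sum(m["support"] for m in self.per_class.values())) == self.n_validation
        assert abs(self.accuracy - np.trace(c) / self.n_validation) < 1e-9
        for m in self.per_class.values():
            p, r = m["precision"], m["recall"]
            expected_f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert abs(m["f1"] - expected_f1) < 1e-9

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.confusion))

    @classmethod
    def from_predictions(cls, y_true, y_pred, model: str = "") -> "EvalReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        conf = _sk_confusion(y_true, y_pred, labels=CLASS_ORDER)
        prec, rec, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=CLASS_ORDER, zero_division=0
        )
        per_class = {
            cls_name: {
                "precision": float(p),
                "recall": float(r),
                "f1": float(f),
                "support": int(s),
            }
            for cls_name, p, r, f, s in zip(CLASS_ORDER, prec, rec, f1, support)
        }
        n = len(y_true)
        return cls(
            confusion=conf,
            per_class=per_class,
            accuracy=float(np.trace(conf) / n),
            n_validation=n,
            model=model,
        )

    @classmethod
    def from_counts(
        cls, correct_dd: int, correct_ww: int, support_dd: int, support_ww: int,
        model: str = "",
    ) -> "EvalReport":
        """Build a report from per-class correct counts and supports (e.g.
        to recompute the arithmetic of a printed confusion matrix)."""
        conf = np.array(
            [
                [correct_dd, support_dd - correct_dd],
                [support_ww - correct_ww, correct_ww],
            ]
        )
        y_true = ["DD"] * support_dd + ["WW"] * support_ww
        y_pred = (
            ["DD"] * correct_dd
            + ["WW"] * (support_dd - correct_dd)
            + ["DD"] * (support_ww - correct_ww)
            + ["WW"] * correct_ww
        )
        report = cls.from_predictions(y_true, y_pred, model=model)
        assert np.array_equal(report.confusion, conf)
        return report

    def to_text(self) -> str:
        """Pretty classification report, metrics to two decimals and
        accuracy to the nearest whole percent."""
        lines = [f"Classification report ({self.model or 'classifier'})"]
        lines.append(f"{'class':>6} {'precision':>9} {'recall':>7} {'f1':>6} {'support':>8}")
        for name in CLASS_ORDER:
            m = self.per_class[name]
            lines.append(
                f"{name:>6} {m['precision']:>9.2f} {m['recall']:>7.2f} "
                f"{m['f1']:>6.2f} {m['support']:>8d}"
            )
        lines.append(f"overall accuracy: {round(100 * self.accuracy)}% "
                     f"({self.n_correct}/{self.n_validation})")
        return "\n".join(lines)


def evaluate(result: TrainResult, X_val: pd.DataFrame, y_val, model: str = "") -> EvalReport:
    """Score a fitted pipeline on the held-out validation subset V."""
    y_val = np.asarray(y_val)
    if len(y_val) == 0:
        raise ValueError("validation subset is empty")
    y_pred = result.pipeline.predict(np.asarray(X_val, float))
    return EvalReport.from_predictions(y_val, y_pred, model=model or "classifier")


def compare_models(report_rf: EvalReport, report_mlp: EvalReport) -> dict:
    """Side-by-side summary of two validation reports.

    Reports with different validation sizes are allowed (independent random
    splits); the mismatch is flagged in the summary.
    """
    delta_correct = report_mlp.n_correct - report_rf.n_correct
    delta_accuracy = report_mlp.accuracy - report_rf.accuracy
    return {
        "rf": {
            "accuracy": report_rf.accuracy,
            "n_correct": report_rf.n_correct,
            "n_validation": report_rf.n_validation,
            "per_class": report_rf.per_class,
        },
        "mlp": {
            "accuracy": report_mlp.accuracy,
            "n_correct": report_mlp.n_correct,
            "n_validation": report_mlp.n_validation,
            "per_class": report_mlp.per_class,
        },
        "delta_correct_mlp_minus_rf": delta_correct,
        "delta_accuracy_points": round(100 * delta_accuracy, 1),
        "same_validation_size": report_rf.n_validation == report_mlp.n_validation,
    }
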