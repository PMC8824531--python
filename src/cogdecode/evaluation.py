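"""Cross-validated evaluation, balanced accuracy, and permutation nulls."""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .features import FeatureConfig, FeatureMatrix, FeaturePipeline
from .multiclass import build_decision_tree, one_vs_rest_voting, predict_tree
from .pipeline import BinaryPipeline, PipelineSettings
from .selection import _cv_folds
from .signal_model import EpochSet

__all__ = [
    "EvaluationReport",
    "LeakageError",
    "balanced_accuracy",
    "cross_validate_pipeline",
    "permutation_chance_level",
    "runtime_profile",
]


class LeakageError(RuntimeError):
    """A transform was fitted on statistics that include test trials."""


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-class recall."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    classes, counts = np.unique(y_true, return_counts=True)
    if counts.min() == 0 or len(y_true) == 0:
        raise ValueError("every true class must be represented")
    recalls = [
        np.mean(y_pred[y_true == c] == c) for c in classes
    ]
    return float(np.mean(recalls))


@dataclass
class EvaluationReport:
    fold_accuracies: list[float]
    mean_accuracy: float
    n_classes: int
    n_trials: int
    config: dict[str, Any] = field(default_factory=dict)
    chance_level: float | None = None
    n_permutations: int | None = None
    percentile: float | None = None
    seed: int | None = None
    stage_seconds: dict[str, float] = field(default_factory=dict)
    selection_logs: list[Any] = field(default_factory=list)
    balance_logs: list[Any] = field(default_factory=list)
    leaky_normalization: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "n_classes": self.n_classes,
            "n_trials": self.n_trials,
            "chance_level": self.chance_level,
            "n_permutations": self.n_permutations,
            "percentile": self.percentile,
            "seed": self.seed,
            "stage_seconds": {k: float(v) for k, v in self.stage_seconds.items()},
            "seconds_per_trial": {
                k: float(v) / max(self.n_trials, 1)
                for k, v in self.stage_seconds.items()
            },
            "selection_logs": self.selection_logs,
            "balance_logs": self.balance_logs,
            "leaky_normalization": self.leaky_normalization,
            "config": self.config,
        }


def _fit_predict_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    settings: PipelineSettings,
    multiclass_method: str,
    cv_folds: int,
    logs: tuple[list, list] | None = None,
) -> np.ndarray:
    classes = np.unique(y_train)
    if classes.size == 2:
        pipe = BinaryPipeline(settings)
        pipe.fit(X_train, y_train)
        if logs is not None:
            logs[0].append(pipe.selection_.to_dict())
            logs[1].append(pipe.balance_log_)
        pred, _ = pipe.predict(X_test)
        return pred
    if multiclass_method == "voting":
        model = one_vs_rest_voting(X_train, y_train, settings=settings)
        pred, _ = model.predict(X_test)
        return pred
    if multiclass_method == "tree":
        tree = build_decision_tree(
            X_train, y_train, settings=settings, cv_folds=cv_folds, seed=settings.seed
        )
        return predict_tree(tree, X_test)
    raise ValueError(f"unknown multiclass method {multiclass_method!r}")


def cross_validate_pipeline(
    data: EpochSet | FeatureMatrix,
    settings: PipelineSettings | None = None,
    feature_config: FeatureConfig | None = None,
    outer_folds: int = 5,
    seed: int = 0,
    multiclass_method: str = "voting",
    labels: np.ndarray | None = None,
    allow_leaky_normalization: bool = False,
    config_echo: dict | None = None,
    prepared: dict | None = None,
) -> EvaluationReport:
    """Stratified outer k-fold evaluation of the full pipeline.

    For ``EpochSet`` input the per-fold order is: band-power normalization
    with training statistics -> CSP fit on training trials -> feature
    selection -> SMOTE -> classifier; test folds are transformed with
    training-fold statistics only.  The paper-faithful whole-dataset
    normalization pool is refused unless ``allow_leaky_normalization`` is
    set, and flagged in the report when used.
    """
    settings = (settings or PipelineSettings()).with_seed(seed)
    stage_seconds: dict[str, float] = {}
    t0 = time.perf_counter()

    from_epochs = isinstance(data, EpochSet)
    if from_epochs:
        y = np.asarray(data.labels) if labels is None else np.asarray(labels)
        feature_config = feature_config or FeatureConfig()
        leaky = feature_config.normalization_pool == "all"
        if leaky and not allow_leaky_normalization:
            raise LeakageError(
                "normalization_pool='all' pools test trials into the z-scoring "
                "statistics; pass allow_leaky_normalization=True to run the "
                "paper-faithful mode anyway"
            )
        if np.unique(y).size > 2 and "csp" in feature_config.families:
            warnings.warn(
                "CSP is a two-class transform; dropping the csp family for "
                "the shared multiclass feature matrix"
            )
            fams = tuple(f for f in feature_config.families if f != "csp")
            feature_config = FeatureConfig(
                **{**feature_config.__dict__, "families": fams}
            )
        pipe = FeaturePipeline(feature_config)
        if prepared is None:
            # ``prepared`` may be supplied to amortize the (trial-independent)
            # wavelet stage across repeated evaluations of the same epochs;
            # it must come from FeaturePipeline(feature_config).prepare(data)
            prepared = pipe.prepare(data)
        stage_seconds["prepare_features"] = time.perf_counter() - t0
    else:
        y = np.asarray(data.labels) if labels is None else np.asarray(labels)
        if y is None:
            raise ValueError("labels required")
        leaky = False

    folds = _cv_folds(y, outer_folds, seed)
    fold_accs: list[float] = []
    sel_logs: list[Any] = []
    bal_logs: list[Any] = []
    t_extract = 0.0
    t_fit = 0.0
    for tr, te in folds:
        if from_epochs:
            t1 = time.perf_counter()
            fm = pipe.extract(prepared, train_idx=tr, labels=y)
            t_extract += time.perf_counter() - t1
            X = fm.X
        else:
            X = data.X
        t1 = time.perf_counter()
        pred = _fit_predict_fold(
            X[tr], y[tr], X[te], settings, multiclass_method,
            cv_folds=settings.sfs_cv_folds, logs=(sel_logs, bal_logs),
        )
        t_fit += time.perf_counter() - t1
        fold_accs.append(balanced_accuracy(y[te], pred))
    stage_seconds["extract_features"] = t_extract
    stage_seconds["fit_predict"] = t_fit
    stage_seconds["total"] = time.perf_counter() - t0

    return EvaluationReport(
        fold_accuracies=fold_accs,
        mean_accuracy=float(np.mean(fold_accs)),
        n_classes=int(np.unique(y).size),
        n_trials=int(len(y)),
        config=config_echo or {},
        seed=seed,
        stage_seconds=stage_seconds,
        selection_logs=sel_logs,
        balance_logs=bal_logs,
        leaky_normalization=bool(leaky),
    )


def permutation_chance_level(
    data: EpochSet | FeatureMatrix,
    settings: PipelineSettings | None = None,
    feature_config: FeatureConfig | None = None,
    n_perm: int = 100,
    percentile: float = 95.0,
    outer_folds: int = 5,
    seed: int = 0,
    multiclass_method: str = "voting",
    return_null: bool = False,
    prepared: dict | None = None,
):
    """Empirical chance level: the given percentile of the label-permutation
    null distribution of mean balanced accuracy."""
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    y = np.asarray(data.labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(y))
        report = cross_validate_pipeline(
            data,
            settings=settings,
            feature_config=feature_config,
            outer_folds=outer_folds,
            seed=seed,
            multiclass_method=multiclass_method,
            labels=y[perm],
            prepared=prepared,
        )
        null[i] = report.mean_accuracy
    level = float(np.percentile(null, percentile))
    if return_null:
        return level, null
    return level


def runtime_profile(report: EvaluationReport) -> dict[str, float]:
    """Seconds-per-trial per pipeline stage (logged, never asserted)."""
    n = max(report.n_trials, 1)
    return {k: v / n for k, v in report.stage_seconds.items()}
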