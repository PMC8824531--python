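"""The binary training pipeline: selection -> balancing -> classifier.

``BinaryPipeline`` is the unit composed by both multiclass schemes and by
the cross-validated evaluator.  The default order selects features on the
original training trials and then SMOTEs the selected-feature space, which
keeps synthetic trials out of Fisher scores and the SFS criterion; a
``balance_first`` mode oversamples before selection instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .balancing import SmoteConfig, smote_oversample
from .classifiers import make_classifier
from .selection import (
    SelectionResult,
    filter_select,
    filter_wrapper_select,
    fisher_scores,
)

__all__ = ["PipelineSettings", "BinaryPipeline"]

SELECTION_METHODS = ("none", "filter", "filter+wrapper")


@dataclass
class PipelineSettings:
    """Knobs of one binary subproblem (shared by all multiclass nodes)."""

    selection: str = "filter+wrapper"
    n_filter: int = 100
    n_select: int = 10
    balance: bool = True
    balance_first: bool = False
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    classifier: str | dict = "naive_bayes"
    sfs_cv_folds: int = 5
    seed: int = 0
    min_trials: int = 20

    def __post_init__(self) -> None:
        if self.selection not in SELECTION_METHODS:
            raise ValueError(
                f"selection must be one of {SELECTION_METHODS}, got "
                f"{self.selection!r}"
            )

    def with_seed(self, seed: int) -> "PipelineSettings":
        return replace(self, seed=seed, smote=replace(self.smote, seed=seed))


class BinaryPipeline:
    """Feature selection + SMOTE + one binary classifier, fitted jointly."""

    def __init__(self, settings: PipelineSettings | None = None):
        self.settings = settings or PipelineSettings()
        self.selection_: SelectionResult | None = None
        self.balance_log_: dict[str, Any] | None = None

    def _select(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        s = self.settings
        n_feat = X.shape[1]
        if s.selection == "none" or n_feat <= s.n_select:
            self.selection_ = SelectionResult(
                selected=list(range(n_feat)),
                criterion_trace=[],
                method="none",
                pool_size=n_feat,
                target_size=n_feat,
            )
        elif s.selection == "filter":
            k = min(s.n_select, n_feat)
            self.selection_ = filter_select(fisher_scores(X, y), k)
        else:
            self.selection_ = filter_wrapper_select(
                X,
                y,
                n_filter=min(s.n_filter, n_feat),
                n_select=min(s.n_select, n_feat),
                classifier_spec=s.classifier,
                cv_folds=s.sfs_cv_folds,
                seed=s.seed,
            )
        return np.array(self.selection_.selected, dtype=int)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BinaryPipeline":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        s = self.settings
        if s.balance and s.balance_first:
            X, y, flags = smote_oversample(X, y, s.smote)
            self._log_balance(y, flags)
            cols = self._select(X, y)
            Xs, ys = X[:, cols], y
        else:
            cols = self._select(X, y)
            Xs, ys = X[:, cols], y
            if s.balance:
                Xs, ys, flags = smote_oversample(Xs, ys, s.smote)
                self._log_balance(ys, flags)
        self.columns_ = cols
        self.classifier_ = make_classifier(s.classifier, seed=s.seed)
        self.classifier_.fit(Xs, ys)
        return self

    def _log_balance(self, y: np.ndarray, flags: np.ndarray) -> None:
        classes, counts = np.unique(y, return_counts=True)
        self.balance_log_ = {
            "counts_after": {str(c): int(n) for c, n in zip(classes, counts)},
            "n_synthetic": int(flags.sum()),
        }

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        return self.classifier_.predict(X[:, self.columns_])

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.classifier_.score_samples(X[:, self.columns_])
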