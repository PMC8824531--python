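"""Fisher-score filtering and sequential forward selection (SFS).

The combined method filters down to ``n_filter`` columns by Fisher score and
then runs the greedy wrapper, whose criterion is mean cross-validated
balanced accuracy of the downstream classifier. Fold assignment is drawn
once per SFS run so candidate comparisons are paired.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SelectionResult",
    "fisher_scores",
    "filter_select",
    "sfs_select",
    "filter_wrapper_select",
]


@dataclass
class SelectionResult:
    selected: list[int]
    criterion_trace: list[float]
    method: str
    pool_size: int
    target_size: int
    seed: int | None = None
    scores: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected": [int(i) for i in self.selected],
            "criterion_trace": [float(v) for v in self.criterion_trace],
            "pool_size": int(self.pool_size),
            "target_size": int(self.target_size),
            "seed": self.seed,
        }


def fisher_scores(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-column class-separability score.

    Binary: ((mu1 - mu)^2 + (mu2 - mu)^2) / (s1^2 + s2^2) with sample
    variances (ddof=1).  With more than 2 classes the sum-over-classes
    generalization sum_c (mu_c - mu)^2 / sum_c s_c^2 is used, which reduces
    to the binary form at 2 classes.  Zero denominators score 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("fisher_scores requires at least 2 classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} needs >= 2 trials for a variance")
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[labels == c]
        num += (Xc.mean(axis=0) - mu) ** 2
        den += Xc.var(axis=0, ddof=1)
    bad = den <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} feature(s) with zero within-class variance; "
            "Fisher score set to 0"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(bad, 0.0, num / np.where(bad, 1.0, den))
    return scores


def filter_select(scores: np.ndarray, k: int) -> SelectionResult:
    """Indices of the k largest scores; ties favor the lower column index."""
    scores = np.asarray(scores, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > scores.size:
        raise ValueError(f"k={k} exceeds feature count {scores.size}")
    order = np.argsort(-scores, kind="stable")
    selected = order[:k].tolist()
    return SelectionResult(
        selected=selected,
        criterion_trace=[float(scores[i]) for i in selected],
        method="filter",
        pool_size=scores.size,
        target_size=k,
        scores=scores,
    )


def _cv_folds(
    labels: np.ndarray, n_folds: int, seed: int, X: np.ndarray | None = None
):
    """One fixed stratified fold assignment; degenerate folds are an error.

    When ``X`` is given, trials are ordered by a content hash before the
    seeded shuffle, which makes the assignment equivariant under trial
    permutation: the same rows land in the same folds regardless of input
    order, so selection results do not depend on how trials are stored.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} trials; "
            f"stratified {n_folds}-fold CV is infeasible"
        )
    n = len(labels)
    if X is not None:
        keys = [
            hashlib.blake2b(
                np.ascontiguousarray(X[i]).tobytes() + repr(labels[i]).encode(),
                digest_size=16,
            ).digest()
            for i in range(n)
        ]
        canonical = np.array(sorted(range(n), key=keys.__getitem__))
    else:
        canonical = np.arange(n)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    for c in classes:
        idx = canonical[labels[canonical] == c]
        idx = idx[rng.permutation(len(idx))]
        fold_of[idx] = np.arange(len(idx)) % n_folds
    return [
        (np.flatnonzero(fold_of != k), np.flatnonzero(fold_of == k))
        for k in range(n_folds)
    ]


def _cv_balanced_accuracy(X, labels, folds, make_classifier) -> float:
    from .evaluation import balanced_accuracy

    accs = []
    for tr, te in folds:
        clf = make_classifier()
        clf.fit(X[tr], labels[tr])
        pred, _ = clf.predict(X[te])
        accs.append(balanced_accuracy(labels[te], pred))
    return float(np.mean(accs))


def sfs_select(
    X: np.ndarray,
    labels: np.ndarray,
    pool: np.ndarray | None = None,
    target_size: int = 10,
    classifier_spec: str | dict = "naive_bayes",
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Greedy forward selection maximizing mean CV balanced accuracy.

    At each step every remaining pool column is tried as an addition; the
    best (ties -> lowest column index) is kept.  The criterion value after
    each addition is recorded in ``criterion_trace``.
    """
    from .classifiers import make_classifier

    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    pool = np.arange(X.shape[1]) if pool is None else np.asarray(pool)
    if target_size > pool.size:
        raise ValueError("target_size exceeds pool size")
    folds = _cv_folds(labels, cv_folds, seed, X=X[:, np.sort(pool)])
    factory = lambda: make_classifier(classifier_spec, seed=seed)

    selected: list[int] = []
    trace: list[float] = []
    remaining = sorted(int(i) for i in pool)
    while len(selected) < target_size:
        best_col, best_score = None, -np.inf
        for col in remaining:
            cols = selected + [col]
            score = _cv_balanced_accuracy(X[:, cols], labels, folds, factory)
            if score > best_score + 1e-12:
                best_col, best_score = col, score
        selected.append(best_col)
        remaining.remove(best_col)
        trace.append(best_score)
    return SelectionResult(
        selected=selected,
        criterion_trace=trace,
        method="sfs",
        pool_size=pool.size,
        target_size=target_size,
        seed=seed,
    )


def filter_wrapper_select(
    X: np.ndarray,
    labels: np.ndarray,
    n_filter: int = 100,
    n_select: int = 10,
    classifier_spec: str | dict = "naive_bayes",
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Fisher filter to ``n_filter`` columns, then SFS down to ``n_select``."""
    if not (n_select <= n_filter <= X.shape[1]):
        raise ValueError("need n_select <= n_filter <= feature count")
    scores = fisher_scores(X, labels)
    filtered = filter_select(scores, n_filter)
    if n_filter == n_select:
        result = filtered
        result.method = "filter+wrapper"
        return result
    result = sfs_select(
        X,
        labels,
        pool=np.array(filtered.selected),
        target_size=n_select,
        classifier_spec=classifier_spec,
        cv_folds=cv_folds,
        seed=seed,
    )
    result.method = "filter+wrapper"
    result.pool_size = X.shape[1]
    return result
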