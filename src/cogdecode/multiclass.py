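"""Multiclass generalization of the binary pipeline.

Two schemes:

* one-vs-rest **voting** — k binary problems (class vs merged rest), each
  with its own feature selection and balancing; the final label is the
  class whose singleton-favoring score is largest.
* **partition tree** — recursive binary splitting of the class set.  At
  each node every 2-partition of the node's classes is trained and scored
  by cross-validated balanced accuracy; the best partition becomes the
  node's split, down to singleton leaves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .pipeline import BinaryPipeline, PipelineSettings
from .selection import _cv_folds

__all__ = [
    "VotingModel",
    "PartitionTree",
    "TreeNode",
    "one_vs_rest_voting",
    "build_decision_tree",
    "predict_tree",
]


def _check_min_trials(labels: np.ndarray, min_trials: int) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    for c, n in zip(classes, counts):
        if n < min_trials:
            raise ValueError(
                f"class {c!r} has {n} trials; at least {min_trials} required"
            )


class VotingModel:
    """One-vs-rest score voting over k binary pipelines."""

    def __init__(self, classes: np.ndarray, pipelines: dict):
        self.classes_ = classes
        self.pipelines_ = pipelines

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Per-trial evidence for each class, shape (trials, k)."""
        return np.column_stack(
            [self.pipelines_[c].score_samples(X) for c in self.classes_]
        )

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = self.scores(X)
        return self.classes_[np.argmax(s, axis=1)], s


def one_vs_rest_voting(
    X: np.ndarray,
    labels: np.ndarray,
    classifier_spec: str | dict | None = None,
    settings: PipelineSettings | None = None,
) -> VotingModel:
    """Train k binary (class vs rest) pipelines on training data.

    Each subproblem codes the singleton class as 1 and the merged rest as
    0, so the binary score is oriented to favor the singleton.
    """
    settings = settings or PipelineSettings()
    if classifier_spec is not None:
        settings = PipelineSettings(**{**settings.__dict__, "classifier": classifier_spec})
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    _check_min_trials(labels, settings.min_trials)
    classes = np.unique(labels)
    pipelines = {}
    for c in classes:
        y_bin = (labels == c).astype(int)
        pipe = BinaryPipeline(settings)
        pipe.fit(X, y_bin)
        pipelines[c] = pipe
    return VotingModel(classes, pipelines)


@dataclass
class TreeNode:
    classes: tuple
    left_classes: tuple | None = None
    right_classes: tuple | None = None
    model: BinaryPipeline | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    partition_scores: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return len(self.classes) == 1

    def to_dict(self) -> dict[str, Any]:
        if self.is_leaf:
            return {"leaf": self.classes[0]}
        return {
            "classes": list(self.classes),
            "left_classes": list(self.left_classes),
            "right_classes": list(self.right_classes),
            "selection": self.model.selection_.to_dict() if self.model else None,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


@dataclass
class PartitionTree:
    root: TreeNode
    classes: tuple

    def n_models(self) -> int:
        def count(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + count(node.left) + count(node.right)

        return count(self.root)


def _partitions(classes: tuple) -> list[tuple[tuple, tuple]]:
    """All unordered 2-partitions, left set containing the smallest class,
    enumerated in deterministic (size, lexicographic) order."""
    rest = classes[1:]
    parts = []
    for r in range(len(rest) + 1):
        for combo in itertools.combinations(rest, r):
            left = (classes[0],) + combo
            right = tuple(c for c in classes if c not in left)
            if right:
                parts.append((left, right))
    return parts


def _node_cv_score(
    X: np.ndarray,
    labels: np.ndarray,
    left: tuple,
    settings: PipelineSettings,
    cv_folds: int,
    seed: int,
) -> float:
    from .evaluation import balanced_accuracy

    y_bin = np.isin(labels, left).astype(int)
    folds = _cv_folds(labels, cv_folds, seed)  # stratify on the full classes
    accs = []
    for tr, te in folds:
        pipe = BinaryPipeline(settings)
        pipe.fit(X[tr], y_bin[tr])
        pred, _ = pipe.predict(X[te])
        accs.append(balanced_accuracy(y_bin[te], pred))
    return float(np.mean(accs))


def build_decision_tree(
    X: np.ndarray,
    labels: np.ndarray,
    classifier_spec: str | dict | None = None,
    settings: PipelineSettings | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> PartitionTree:
    """Exhaustive-partition binary decision tree (feasible for k <= ~5).

    At every internal node, all 2^(|S|-1) - 1 candidate partitions are
    trained through the full binary pipeline and scored by stratified CV
    balanced accuracy on the node's training trials; ties keep the first
    candidate in the deterministic enumeration order.
    """
    settings = settings or PipelineSettings()
    if classifier_spec is not None:
        settings = PipelineSettings(**{**settings.__dict__, "classifier": classifier_spec})
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    _check_min_trials(labels, settings.min_trials)
    classes = tuple(np.unique(labels).tolist())

    def grow(idx: np.ndarray) -> TreeNode:
        sub = tuple(np.unique(labels[idx]).tolist())
        node = TreeNode(classes=sub)
        if len(sub) == 1:
            return node
        candidates = _partitions(sub)
        if len(candidates) == 1:
            best_left, best_right = candidates[0]
        else:
            best_left = best_right = None
            best_score = -np.inf
            for left, right in candidates:
                score = _node_cv_score(
                    X[idx], labels[idx], left, settings, cv_folds, seed
                )
                node.partition_scores[(left, right)] = score
                if score > best_score + 1e-12:
                    best_left, best_right, best_score = left, right, score
        node.left_classes, node.right_classes = best_left, best_right
        y_bin = np.isin(labels[idx], best_left).astype(int)
        node.model = BinaryPipeline(settings).fit(X[idx], y_bin)
        node.left = grow(idx[np.isin(labels[idx], best_left)])
        node.right = grow(idx[np.isin(labels[idx], best_right)])
        return node

    return PartitionTree(root=grow(np.arange(len(labels))), classes=classes)


def predict_tree(tree: PartitionTree, X: np.ndarray) -> np.ndarray:
    """Route each trial root-to-leaf through the node models."""
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape[0], dtype=np.asarray(tree.classes).dtype)

    def route(node: TreeNode, idx: np.ndarray) -> None:
        if node.is_leaf:
            out[idx] = node.classes[0]
            return
        pred, _ = node.model.predict(X[idx])
        go_left = pred == 1  # left classes were coded 1 at fit time
        route(node.left, idx[go_left])
        route(node.right, idx[~go_left])

    route(tree.root, np.arange(X.shape[0]))
    return out
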