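"""SMOTE oversampling so every class matches the majority count.

Synthetic trials are convex combinations x + u (x' - x) of a minority trial
and one of its k nearest minority neighbors; creation cycles round-robin
over the minority trials in a seed-fixed order.  Applied to training data
only — neighbor search never sees test trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SmoteConfig", "smote_oversample"]


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0
    target: str = "match-majority"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target != "match-majority":
            raise ValueError("only 'match-majority' balancing is supported")


def smote_oversample(
    X: np.ndarray, labels: np.ndarray, cfg: SmoteConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample every non-majority class up to the majority count.

    Returns ``(X_aug, labels_aug, synthetic_flag)`` where original rows come
    first, in their input order, and ``synthetic_flag`` marks created rows.
    """
    cfg = cfg or SmoteConfig()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    majority = counts.max()
    rng = np.random.default_rng(cfg.seed)

    new_rows, new_labels = [], []
    for c, count in zip(classes, counts):
        need = majority - count
        if need == 0:
            continue
        if count < 2:
            raise ValueError(
                f"class {c!r} has a single trial; SMOTE needs >= 2"
            )
        k = cfg.k_neighbors
        if k >= count:
            warnings.warn(
                f"k_neighbors={k} >= class size {count}; clamping to {count - 1}"
            )
            k = count - 1
        Xc = X[labels == c]
        d = cdist(Xc, Xc)
        np.fill_diagonal(d, np.inf)
        neighbor_idx = np.argsort(d, axis=1, kind="stable")[:, :k]
        order = rng.permutation(count)
        for j in range(need):
            i = order[j % count]
            nb = neighbor_idx[i, rng.integers(k)]
            u = rng.uniform()
            new_rows.append(Xc[i] + u * (Xc[nb] - Xc[i]))
            new_labels.append(c)

    if not new_rows:
        return X, labels, np.zeros(len(labels), dtype=bool)
    X_aug = np.vstack([X, np.array(new_rows)])
    labels_aug = np.concatenate([labels, np.array(new_labels, dtype=labels.dtype)])
    flags = np.zeros(len(labels_aug), dtype=bool)
    flags[len(labels):] = True
    return X_aug, labels_aug, flags
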