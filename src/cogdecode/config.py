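"""Run configuration: one YAML-serializable object driving the whole run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .balancing import SmoteConfig
from .features import FAMILY_ORDER, FeatureConfig
from .pipeline import PipelineSettings
from .signal_model import EpochSet
from .synthetic import SyntheticSpec

__all__ = ["PipelineConfig", "validate_input"]


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    input_path: str | None = None
    synthetic: dict | None = None  # SyntheticSpec.to_dict() payload
    families: tuple[str, ...] = FAMILY_ORDER
    selection: str = "filter+wrapper"
    n_filter: int = 100
    n_select: int = 10
    balance: bool = True
    smote_k: int = 5
    classifier: str = "naive_bayes"
    multiclass: str = "voting"  # "voting" | "tree"
    cv_folds: int = 5
    sfs_cv_folds: int = 5
    permutations: int = 0
    seed: int = 0
    min_trials: int = 20
    normalization_pool: str = "train"
    allow_leaky_normalization: bool = False
    n_bins: int = 5
    ar_order: int = 4
    csp_components: int | None = None
    band_agg: str = "sum"
    fs_out: float = 50.25
    n_cycles: float = 5.0
    crop_ms: tuple[float, float] = (0.0, 2000.0)
    window_width_ms: float = 400.0
    window_step_ms: float = 200.0

    def __post_init__(self) -> None:
        errors = []
        unknown = set(self.families) - set(FAMILY_ORDER)
        if unknown:
            errors.append(f"families: unknown {sorted(unknown)}")
        if self.selection not in ("none", "filter", "filter+wrapper"):
            errors.append(f"selection: {self.selection!r}")
        if self.multiclass not in ("voting", "tree"):
            errors.append(f"multiclass: {self.multiclass!r}")
        if self.classifier not in ("naive_bayes", "logistic", "lasso", "linear_svm"):
            errors.append(f"classifier: {self.classifier!r}")
        if self.input_path is None and self.synthetic is None:
            errors.append("one of input_path or synthetic is required")
        if errors:
            raise ValueError("invalid config keys: " + "; ".join(errors))
        self.families = tuple(self.families)
        self.crop_ms = tuple(self.crop_ms)

    # -- derived objects ----------------------------------------------------

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            families=self.families,
            n_cycles=self.n_cycles,
            fs_out=self.fs_out,
            crop_ms=self.crop_ms,
            window_start_ms=self.crop_ms[0],
            window_end_ms=self.crop_ms[1],
            window_width_ms=self.window_width_ms,
            window_step_ms=self.window_step_ms,
            n_bins=self.n_bins,
            ar_order=self.ar_order,
            csp_components=self.csp_components,
            band_agg=self.band_agg,
            normalization_pool=self.normalization_pool,
        )

    def pipeline_settings(self) -> PipelineSettings:
        return PipelineSettings(
            selection=self.selection,
            n_filter=self.n_filter,
            n_select=self.n_select,
            balance=self.balance,
            smote=SmoteConfig(k_neighbors=self.smote_k, seed=self.seed),
            classifier=self.classifier,
            sfs_cv_folds=self.sfs_cv_folds,
            seed=self.seed,
            min_trials=self.min_trials,
        )

    def synthetic_spec(self) -> SyntheticSpec:
        if self.synthetic is None:
            raise ValueError("config has no synthetic block")
        return SyntheticSpec.from_dict(self.synthetic)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["families"] = list(self.families)
        d["crop_ms"] = list(self.crop_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise ValueError(f"invalid config keys: {sorted(bad)}")
        if "families" in d:
            d["families"] = tuple(d["families"])
        if "crop_ms" in d:
            d["crop_ms"] = tuple(d["crop_ms"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_input(epochs: EpochSet, config: PipelineConfig) -> list[dict]:
    """Non-mutating input checks; returns the list of violations.

    Checks the minimum-trials-per-class rule, finiteness (locating any
    offending sample), and region coverage of the channel set.
    """
    violations: list[dict] = []
    classes, counts = np.unique(epochs.labels, return_counts=True)
    if classes.size < 2:
        violations.append({"kind": "classes", "detail": "fewer than 2 classes"})
    for c, n in zip(classes, counts):
        if n < config.min_trials:
            violations.append(
                {
                    "kind": "min_trials",
                    "class": c.item() if hasattr(c, "item") else c,
                    "count": int(n),
                    "required": config.min_trials,
                }
            )
    bad = ~np.isfinite(epochs.data)
    if bad.any():
        trial, channel, sample = (int(v[0]) for v in np.nonzero(bad))
        violations.append(
            {
                "kind": "non_finite",
                "trial": trial,
                "channel": channel,
                "sample": sample,
            }
        )
    needs_regions = any(
        f in config.families for f in ("correlation", "phase_sync", "ar")
    )
    if needs_regions:
        from .signal_model import REGION_ORDER, default_region_map

        rmap = default_region_map(epochs.channel_names)
        idx = rmap.indices(epochs.channel_names)
        for region in REGION_ORDER:
            if not idx[region]:
                violations.append({"kind": "empty_region", "region": region})
    return violations
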