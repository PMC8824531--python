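"""Eight feature families over (band x window x channel/region) cells.

Families and their loci:

==============  =========================  =================
family          locus                      values per cell
==============  =========================  =================
mean            channel                    1
variance        channel                    1
entropy         channel                    1
phase           channel                    1
correlation     region pair (6)            1
phase_sync      region pair (6)            1
ar              region (4)                 p coefficients
csp             projected component        1
==============  =========================  =================

With 32 channels, 4 bands, 9 windows, 4 regions, AR order 4 and all 32 CSP
components this yields 4*1152 + 2*216 + 576 + 1152 = 6768 columns.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg as _linalg
from scipy.signal import hilbert

from .signal_model import (
    REGION_ORDER,
    BandPowerTensor,
    EpochSet,
    RegionMap,
    WindowGrid,
    average_regions,
    band_power_from_epochs,
    default_region_map,
    make_window_grid,
    normalize_band_power,
    window_sample_indices,
)

__all__ = [
    "FeatureDescriptor",
    "FeatureMatrix",
    "CSPModel",
    "FeatureConfig",
    "FAMILY_ORDER",
    "REGION_PAIRS",
    "extract_mean",
    "extract_variance",
    "extract_entropy",
    "extract_phase",
    "extract_correlation",
    "extract_phase_sync",
    "extract_ar",
    "fit_csp",
    "extract_csp_features",
    "extract_all",
    "FeaturePipeline",
]

FAMILY_ORDER: tuple[str, ...] = (
    "mean",
    "variance",
    "entropy",
    "phase",
    "correlation",
    "phase_sync",
    "ar",
    "csp",
)

REGION_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(REGION_ORDER, 2)
)


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identifies one feature-matrix column."""

    family: str
    band: str
    window: int
    locus: str
    coef: int | None = None

    def __str__(self) -> str:
        tail = f":{self.coef}" if self.coef is not None else ""
        return f"{self.family}|{self.band}|w{self.window}|{self.locus}{tail}"


@dataclass
class FeatureMatrix:
    """Trials x features with one descriptor per column."""

    X: np.ndarray
    descriptors: list[FeatureDescriptor]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != len(self.descriptors):
            raise ValueError("one descriptor per column required")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def family_columns(self, family: str) -> np.ndarray:
        return np.flatnonzero(
            np.array([d.family == family for d in self.descriptors])
        )


# ---------------------------------------------------------------------------
# channel-level statistical families


def _window_stack(bp: BandPowerTensor, grid: WindowGrid) -> list[np.ndarray]:
    """Per-window views of the tensor, each (trials, channels, bands, n_w)."""
    slices = window_sample_indices(grid, bp.times_ms, bp.fs_out)
    return [bp.bp[:, :, :, idx] for idx in slices]


def _columns_from_cells(
    per_window: list[np.ndarray],
    family: str,
    bp: BandPowerTensor,
    loci: Sequence[str],
    coefs: Sequence[int | None] = (None,),
) -> tuple[np.ndarray, list[FeatureDescriptor]]:
    """Assemble columns in canonical (band, window, locus, coef) order.

    ``per_window[w]`` has shape (trials, n_loci, n_bands[, n_coef]).
    """
    n_trials = per_window[0].shape[0]
    cols, desc = [], []
    for bi, band in enumerate(bp.band_names):
        for wi, vals in enumerate(per_window):
            for li, locus in enumerate(loci):
                cell = vals[:, li, bi]
                if cell.ndim == 1:
                    cell = cell[:, None]
                for ci, coef in enumerate(coefs):
                    cols.append(cell[:, ci])
                    desc.append(
                        FeatureDescriptor(family, band, wi, locus, coef)
                    )
    X = np.column_stack(cols) if cols else np.empty((n_trials, 0))
    return X, desc


def extract_mean(bp: BandPowerTensor, grid: WindowGrid):
    """Arithmetic mean of in-window power per (channel, window, band)."""
    per_w = [w.mean(axis=-1) for w in _window_stack(bp, grid)]
    return _columns_from_cells(per_w, "mean", bp, bp.channel_names)


def extract_variance(bp: BandPowerTensor, grid: WindowGrid):
    """Sample variance (ddof=1) of in-window power."""
    per_w = [w.var(axis=-1, ddof=1) for w in _window_stack(bp, grid)]
    return _columns_from_cells(per_w, "variance", bp, bp.channel_names)


def _entropy_last_axis(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Shannon entropy (bits) of an equal-width histogram over each cell's
    own min-max range, vectorized over all leading axes."""
    n = x.shape[-1]
    mn = x.min(axis=-1, keepdims=True)
    rng = x.max(axis=-1, keepdims=True) - mn
    degenerate = rng[..., 0] <= 0
    safe_rng = np.where(rng > 0, rng, 1.0)
    idx = np.floor((x - mn) / safe_rng * n_bins).astype(np.intp)
    np.clip(idx, 0, n_bins - 1, out=idx)
    flat = idx.reshape(-1, n)
    offsets = np.arange(flat.shape[0])[:, None] * n_bins
    counts = np.bincount(
        (flat + offsets).ravel(), minlength=flat.shape[0] * n_bins
    ).reshape(flat.shape[0], n_bins)
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
    h = h.reshape(x.shape[:-1])
    h[degenerate] = 0.0
    return h


def extract_entropy(bp: BandPowerTensor, grid: WindowGrid, n_bins: int = 5):
    """Histogram Shannon entropy of in-window power, in bits."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    per_w = [_entropy_last_axis(w, n_bins) for w in _window_stack(bp, grid)]
    return _columns_from_cells(per_w, "entropy", bp, bp.channel_names)


# ---------------------------------------------------------------------------
# phase families


def instantaneous_phase(bp: BandPowerTensor) -> np.ndarray:
    """Phase of the analytic signal of each mean-centered band-power series.

    Shape (trials, channels, bands, time).  Invariant to the per-band affine
    normalization, so it can be computed once per dataset.
    """
    x = bp.bp - bp.bp.mean(axis=-1, keepdims=True)
    return np.angle(hilbert(x, axis=-1))


def _resultant_length(angles: np.ndarray) -> np.ndarray:
    return np.abs(np.exp(1j * angles).mean(axis=-1))


def extract_phase(
    bp: BandPowerTensor, grid: WindowGrid, phases: np.ndarray | None = None
):
    """Mean resultant length of in-window instantaneous phase, in [0, 1]."""
    if phases is None:
        phases = instantaneous_phase(bp)
    slices = window_sample_indices(grid, bp.times_ms, bp.fs_out)
    per_w = [_resultant_length(phases[:, :, :, idx]) for idx in slices]
    return _columns_from_cells(per_w, "phase", bp, bp.channel_names)


def extract_phase_sync(
    region_bp: BandPowerTensor, grid: WindowGrid, phases: np.ndarray | None = None
):
    """Phase-locking value per region pair: |mean exp(i(phi1 - phi2))|."""
    if phases is None:
        phases = instantaneous_phase(region_bp)
    names = region_bp.channel_names
    slices = window_sample_indices(grid, region_bp.times_ms, region_bp.fs_out)
    pair_idx = [(names.index(a), names.index(b)) for a, b in REGION_PAIRS]
    per_w = []
    for idx in slices:
        diffs = np.stack(
            [phases[:, i, :, :][..., idx] - phases[:, j, :, :][..., idx]
             for i, j in pair_idx],
            axis=1,
        )
        per_w.append(_resultant_length(diffs))
    loci = [f"{a}~{b}" for a, b in REGION_PAIRS]
    return _columns_from_cells(per_w, "phase_sync", region_bp, loci)


# ---------------------------------------------------------------------------
# region correlation and AR families


def extract_correlation(region_bp: BandPowerTensor, grid: WindowGrid):
    """Pearson r between region power series of the same window and band.

    Zero-variance series yield r = 0 with a warning (degeneracy rule).
    """
    names = region_bp.channel_names
    pair_idx = [(names.index(a), names.index(b)) for a, b in REGION_PAIRS]
    per_w = []
    warned = False
    for w in _window_stack(region_bp, grid):
        c = w - w.mean(axis=-1, keepdims=True)
        sd = np.sqrt((c**2).sum(axis=-1))
        vals = []
        for i, j in pair_idx:
            denom = sd[:, i] * sd[:, j]
            num = (c[:, i] * c[:, j]).sum(axis=-1)
            bad = denom <= 0
            if bad.any() and not warned:
                warnings.warn("zero-variance series in correlation; r set to 0")
                warned = True
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(bad, 0.0, num / np.where(bad, 1.0, denom))
            vals.append(r)
        per_w.append(np.stack(vals, axis=1))
    loci = [f"{a}~{b}" for a, b in REGION_PAIRS]
    return _columns_from_cells(per_w, "correlation", region_bp, loci)


def _ar_coefficients(series: np.ndarray, order: int) -> np.ndarray:
    """Least-squares AR(p) on the lagged design, batched over leading axes.

    x[n] = sum_i alpha_i x[n-i] + u[n]; degenerate designs return zeros.
    """
    *lead, n = series.shape
    if n <= order + 1:
        raise ValueError(f"window has {n} samples; AR({order}) needs > {order + 1}")
    flat = series.reshape(-1, n)
    # design: rows n=order..n-1, columns x[n-1], ..., x[n-order]
    cols = [flat[:, order - i : n - i] for i in range(1, order + 1)]
    A = np.stack(cols, axis=-1)  # (cells, n-order, order)
    y = flat[:, order:]
    G = A.transpose(0, 2, 1) @ A
    rhs = (A.transpose(0, 2, 1) @ y[:, :, None])[..., 0]
    coef = np.zeros((flat.shape[0], order))
    sv = np.linalg.svd(G, compute_uv=False)
    ok = sv[:, -1] > 1e-10 * np.maximum(sv[:, 0], 1e-300)
    if not ok.all():
        warnings.warn("rank-deficient AR design; coefficients set to 0")
    if ok.any():
        coef[ok] = np.linalg.solve(G[ok], rhs[ok][:, :, None])[..., 0]
    return coef.reshape(*lead, order)


def extract_ar(region_bp: BandPowerTensor, grid: WindowGrid, order: int = 4):
    """AR(p) coefficients of the in-window region power series."""
    per_w = [_ar_coefficients(w, order) for w in _window_stack(region_bp, grid)]
    coefs = list(range(1, order + 1))
    return _columns_from_cells(
        per_w, "ar", region_bp, region_bp.channel_names, coefs
    )


# ---------------------------------------------------------------------------
# CSP


@dataclass
class CSPModel:
    """Per-(band, window) spatial filters for one class pair.

    Filter columns are ordered by decreasing generalized eigenvalue of
    (C1bar, C1bar + C2bar); they simultaneously diagonalize both matrices.
    """

    filters: dict[tuple[int, int], np.ndarray]
    class_pair: tuple
    band_names: list[str]
    n_windows: int
    covs: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )


def _trial_covariances(w: np.ndarray) -> np.ndarray:
    """Per-trial channel covariance (ddof=1) of (trials, C, n) windows."""
    c = w - w.mean(axis=-1, keepdims=True)
    return c @ c.transpose(0, 2, 1) / (w.shape[-1] - 1)


def csp_eig(C1: np.ndarray, C2: np.ndarray, n_components: int | None = None):
    """Solve the two-class spatial-filter eigenproblem.

    Returns (W, eigvals) with W columns sorted by decreasing eigenvalue of
    the pencil (C1, C1 + C2); eigvals are the Rayleigh quotients
    w'C1w / w'(C1+C2)w in (0, 1).
    """
    n = C1.shape[0]
    denom = C1 + C2
    try:
        _linalg.cholesky(denom)
    except _linalg.LinAlgError:
        lam = 1e-6 * np.trace(denom) / n
        lam = lam if lam > 0 else 1e-10
        warnings.warn("singular pooled covariance; applying diagonal ridge")
        C1 = C1 + lam * np.eye(n)
        C2 = C2 + lam * np.eye(n)
        denom = C1 + C2
    vals, vecs = _linalg.eigh(C1, denom)
    order = np.argsort(vals)[::-1]
    W = vecs[:, order]
    if n_components is not None:
        W = W[:, :n_components]
    return W, vals[order][: W.shape[1]]


def fit_csp(
    bp: BandPowerTensor,
    grid: WindowGrid,
    labels: np.ndarray,
    train_idx: np.ndarray | None = None,
    n_components: int | None = None,
) -> CSPModel:
    """Fit per-(band, window) CSP filters on the training trials only."""
    labels = np.asarray(labels)
    if train_idx is None:
        train_idx = np.arange(bp.n_trials)
    train_idx = np.asarray(train_idx)
    y = labels[train_idx]
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("CSP requires exactly 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"CSP needs >= 2 training trials per class (class {c})")
    slices = window_sample_indices(grid, bp.times_ms, bp.fs_out)
    filters, covs = {}, {}
    for bi in range(len(bp.band_names)):
        for wi, idx in enumerate(slices):
            w = bp.bp[train_idx][:, :, bi, :][:, :, idx]
            tc = _trial_covariances(w)
            C1 = tc[y == classes[0]].mean(axis=0)
            C2 = tc[y == classes[1]].mean(axis=0)
            W, _ = csp_eig(C1, C2, n_components)
            filters[(bi, wi)] = W
            covs[(bi, wi)] = (C1, C2)
    return CSPModel(
        filters=filters,
        class_pair=(classes[0], classes[1]),
        band_names=bp.band_names,
        n_windows=len(grid),
        covs=covs,
    )


def extract_csp_features(bp: BandPowerTensor, grid: WindowGrid, model: CSPModel):
    """Variance of each spatially filtered in-window series."""
    if model.band_names != bp.band_names or model.n_windows != len(grid):
        raise ValueError("CSP model was fitted on a different band/window grid")
    slices = window_sample_indices(grid, bp.times_ms, bp.fs_out)
    n_comp = next(iter(model.filters.values())).shape[1]
    loci = [f"comp{k}" for k in range(n_comp)]
    per_w: list[np.ndarray] = []
    for wi, idx in enumerate(slices):
        vals = np.empty((bp.n_trials, n_comp, len(bp.band_names)))
        for bi in range(len(bp.band_names)):
            W = model.filters[(bi, wi)]
            proj = np.einsum("ck,tcn->tkn", W, bp.bp[:, :, bi, :][:, :, idx])
            vals[:, :, bi] = proj.var(axis=-1, ddof=1)
        per_w.append(vals)
    return _columns_from_cells(per_w, "csp", bp, loci)


# ---------------------------------------------------------------------------
# assembly


@dataclass
class FeatureConfig:
    """Everything needed to turn an EpochSet into a FeatureMatrix."""

    families: tuple[str, ...] = FAMILY_ORDER
    bands: dict[str, tuple[float, float]] | None = None
    n_cycles: float = 5.0
    fs_out: float = 50.25
    crop_ms: tuple[float, float] = (0.0, 2000.0)
    window_start_ms: float = 0.0
    window_end_ms: float = 2000.0
    window_width_ms: float = 400.0
    window_step_ms: float = 200.0
    n_bins: int = 5
    ar_order: int = 4
    csp_components: int | None = None
    band_agg: str = "sum"
    normalization_pool: str = "train"  # "train" | "all"
    region_map: RegionMap | None = None

    def __post_init__(self) -> None:
        unknown = set(self.families) - set(FAMILY_ORDER)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        if self.normalization_pool not in ("train", "all"):
            raise ValueError("normalization_pool must be 'train' or 'all'")

    def grid(self) -> WindowGrid:
        return make_window_grid(
            self.window_start_ms,
            self.window_end_ms,
            self.window_width_ms,
            self.window_step_ms,
        )


_CHANNEL_FAMILIES = ("mean", "variance", "entropy", "phase")
_REGION_FAMILIES = ("correlation", "phase_sync", "ar")


class FeaturePipeline:
    """Splits extraction into a trial-independent ``prepare`` stage (wavelet
    transform + band aggregation + phase) and a fold-dependent ``extract``
    stage (normalization with training statistics, CSP, windows), so
    cross-validation does not repeat the wavelet transform per fold."""

    def __init__(self, config: FeatureConfig | None = None):
        self.config = config or FeatureConfig()

    def prepare(self, epochs: EpochSet) -> dict:
        cfg = self.config
        raw = band_power_from_epochs(
            epochs,
            bands=cfg.bands,
            n_cycles=cfg.n_cycles,
            fs_out=cfg.fs_out,
            crop_ms=cfg.crop_ms,
            agg=cfg.band_agg,
        )
        rmap = cfg.region_map or default_region_map(epochs.channel_names)
        prepared = {"raw": raw, "rmap": rmap, "labels": np.asarray(epochs.labels)}
        if any(f in cfg.families for f in ("correlation", "phase_sync", "ar")):
            prepared["raw_regions"] = average_regions(raw, rmap)
        if "phase" in cfg.families:
            prepared["phases"] = instantaneous_phase(raw)
        if "phase_sync" in cfg.families:
            prepared["region_phases"] = instantaneous_phase(
                prepared["raw_regions"]
            )
        return prepared

    def extract(
        self,
        prepared: dict,
        train_idx: np.ndarray | None = None,
        labels: np.ndarray | None = None,
    ) -> FeatureMatrix:
        cfg = self.config
        grid = cfg.grid()
        raw: BandPowerTensor = prepared["raw"]
        labels = prepared["labels"] if labels is None else np.asarray(labels)
        if train_idx is None or cfg.normalization_pool == "all":
            pool = np.arange(raw.n_trials)
        else:
            pool = np.asarray(train_idx)
        bp = normalize_band_power(raw, pool=pool)
        region_bp = None
        if "raw_regions" in prepared:
            region_bp = average_regions(bp, prepared["rmap"])

        blocks: list[tuple[np.ndarray, list[FeatureDescriptor]]] = []
        for family in FAMILY_ORDER:
            if family not in cfg.families:
                continue
            if family == "mean":
                blocks.append(extract_mean(bp, grid))
            elif family == "variance":
                blocks.append(extract_variance(bp, grid))
            elif family == "entropy":
                blocks.append(extract_entropy(bp, grid, cfg.n_bins))
            elif family == "phase":
                blocks.append(extract_phase(bp, grid, prepared.get("phases")))
            elif family == "correlation":
                blocks.append(extract_correlation(region_bp, grid))
            elif family == "phase_sync":
                blocks.append(
                    extract_phase_sync(
                        region_bp, grid, prepared.get("region_phases")
                    )
                )
            elif family == "ar":
                blocks.append(extract_ar(region_bp, grid, cfg.ar_order))
            elif family == "csp":
                model = fit_csp(
                    bp, grid, labels, train_idx, cfg.csp_components
                )
                blocks.append(extract_csp_features(bp, grid, model))
        X = np.concatenate([b[0] for b in blocks], axis=1)
        desc = [d for b in blocks for d in b[1]]
        return FeatureMatrix(X=X, descriptors=desc, labels=labels)


def extract_all(
    epochs: EpochSet,
    config: FeatureConfig | None = None,
    train_idx: np.ndarray | None = None,
) -> FeatureMatrix:
    """One-shot epochs -> FeatureMatrix.

    CSP (when requested) is fitted on ``train_idx`` only; with the default
    ``normalization_pool='train'`` the band z-scoring statistics also come
    from the training trials.
    """
    pipe = FeaturePipeline(config)
    prepared = pipe.prepare(epochs)
    return pipe.extract(prepared, train_idx=train_idx)
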