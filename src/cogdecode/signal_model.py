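"""Epoched-recording data model and the normalized band-power substrate.

The canonical flow is::

    EpochSet --morlet_transform--> TimeFrequencyPower
             --aggregate_band_power--> BandPowerTensor (raw)
             --normalize_band_power--> BandPowerTensor (z-scored per band)
             --average_regions------> BandPowerTensor (4 region series)

All downstream feature families consume the normalized band-power tensor,
optionally collapsed to the four scalp regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _sig
from scipy.fft import irfft, next_fast_len, rfft

__all__ = [
    "EpochSet",
    "RegionMap",
    "TimeFrequencyPower",
    "BandPowerTensor",
    "WindowGrid",
    "DEFAULT_BANDS",
    "DEFAULT_FREQS",
    "REGION_ORDER",
    "default_montage_32",
    "default_region_map",
    "morlet_kernel",
    "morlet_transform",
    "aggregate_band_power",
    "normalize_band_power",
    "average_regions",
    "make_window_grid",
    "window_sample_indices",
]

#: Band edges are closed intervals in Hz; grid lines between bands (e.g.
#: 31-34 Hz) belong to no band.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (3.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (35.0, 80.0),
}

#: 78 linearly spaced analysis frequencies, 3-80 Hz.
DEFAULT_FREQS: np.ndarray = np.linspace(3.0, 80.0, 78)

REGION_ORDER: tuple[str, ...] = (
    "frontal-left",
    "frontal-right",
    "posterior-left",
    "posterior-right",
)

_FRONTAL_FAMILIES = ("AF", "FP", "FC", "F")
_POSTERIOR_FAMILIES = ("CP", "PO", "C", "P", "O", "T")


@dataclass
class EpochSet:
    """Labeled multichannel voltage epochs (trials x channels x samples)."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one trial")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("one name per channel required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs

    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


class RegionMap:
    """Assignment of channels to the four scalp regions.

    Channels mapped to ``"excluded"`` take no part in region features.
    """

    def __init__(self, mapping: Mapping[str, str]):
        for ch, region in mapping.items():
            if region not in REGION_ORDER and region != "excluded":
                raise ValueError(f"unknown region {region!r} for channel {ch!r}")
        self.mapping = dict(mapping)

    def region_channels(self, region: str) -> list[str]:
        return [ch for ch, r in self.mapping.items() if r == region]

    def indices(self, channel_names: Sequence[str]) -> dict[str, list[int]]:
        """Per-region channel indices into ``channel_names``."""
        out: dict[str, list[int]] = {r: [] for r in REGION_ORDER}
        for i, ch in enumerate(channel_names):
            region = self.mapping.get(ch, "excluded")
            if region != "excluded":
                out[region].append(i)
        return out


def default_montage_32() -> list[str]:
    """Extended 10-20 names for the default 32-channel montage."""
    return [
        "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
        "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
        "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
        "PO3", "PO4", "O1", "Oz", "O2",
    ]


def default_region_map(channel_names: Sequence[str] | None = None) -> RegionMap:
    """Region assignment by 10-20 naming conventions.

    Laterality follows the odd/even electrode-number rule (odd = left);
    anterior/posterior follows the label family (AF/Fp/F/FC = frontal, the
    rest = posterior).  Midline ``z`` channels are excluded.
    """
    if channel_names is None:
        channel_names = default_montage_32()
    mapping: dict[str, str] = {}
    for ch in channel_names:
        up = ch.upper()
        digits = "".join(c for c in up if c.isdigit())
        if up.endswith("Z") or not digits:
            mapping[ch] = "excluded"
            continue
        side = "left" if int(digits) % 2 == 1 else "right"
        family = up.rstrip("0123456789")
        if family in _FRONTAL_FAMILIES:
            mapping[ch] = f"frontal-{side}"
        elif family in _POSTERIOR_FAMILIES or family.startswith(_POSTERIOR_FAMILIES):
            mapping[ch] = f"posterior-{side}"
        else:
            mapping[ch] = "excluded"
    return RegionMap(mapping)


@dataclass
class TimeFrequencyPower:
    """Nonnegative wavelet power, trials x channels x frequencies x time."""

    power: np.ndarray
    freqs_hz: np.ndarray
    fs_out: float
    times_ms: np.ndarray
    coefs: np.ndarray | None = None  # complex coefficients, optional

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass
class BandPowerTensor:
    """Per-band power, trials x channels(/regions) x bands x time."""

    bp: np.ndarray
    bands: dict[str, tuple[float, float]]
    fs_out: float
    times_ms: np.ndarray
    channel_names: list[str]
    normalized: bool = False
    norm_stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def band_names(self) -> list[str]:
        return list(self.bands)

    @property
    def n_trials(self) -> int:
        return self.bp.shape[0]


@dataclass(frozen=True)
class WindowGrid:
    """Ordered half-open [start, end) analysis windows in ms."""

    windows: tuple[tuple[float, float], ...]
    step_ms: float
    width_ms: float

    def __len__(self) -> int:
        return len(self.windows)


def make_window_grid(
    start_ms: float, end_ms: float, width_ms: float, step_ms: float
) -> WindowGrid:
    """All windows [start + k*step, start + k*step + width) inside the span."""
    if width_ms <= 0 or step_ms <= 0:
        raise ValueError("window width and step must be positive")
    if width_ms > end_ms - start_ms:
        raise ValueError("window width exceeds the analysis span")
    windows = []
    k = 0
    while start_ms + k * step_ms + width_ms <= end_ms + 1e-9:
        a = start_ms + k * step_ms
        windows.append((a, a + width_ms))
        k += 1
    return WindowGrid(tuple(windows), step_ms=step_ms, width_ms=width_ms)


def window_sample_indices(
    grid: WindowGrid, times_ms: np.ndarray, fs_out: float | None = None
) -> list[np.ndarray]:
    """Indices of samples falling in each half-open window a <= t < b.

    When ``fs_out`` is given, every window is truncated to its nominal
    sample count floor(width * fs_out): at 50.25 Hz a 400-ms window spans
    20.1 sample periods, so time membership alone would hand an occasional
    21st sample to some windows.  Fixing the count keeps all windows
    statistically comparable (and matches the canonical 20-samples-per-
    window configuration).
    """
    cap = None
    if fs_out is not None:
        cap = int(np.floor(grid.width_ms * fs_out / 1000.0))
    out = []
    for a, b in grid.windows:
        idx = np.flatnonzero((times_ms >= a) & (times_ms < b))
        if cap is not None:
            idx = idx[:cap]
        if idx.size < 2:
            raise ValueError(
                f"window [{a}, {b}) maps to {idx.size} samples; need >= 2"
            )
        out.append(idx)
    return out


def morlet_kernel(freq: float, n_cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet sampled at ``fs``, truncated at +-3 sigma_t.

    The Gaussian envelope has sigma_t = n_cycles / (2 pi f); the kernel is
    L2-normalized so power estimates are comparable across frequencies.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.floor(3.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return kernel / np.sqrt(np.sum(np.abs(kernel) ** 2))


def _resample_factors(fs_in: float, fs_out: float) -> tuple[int, int]:
    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return frac.numerator, frac.denominator


def _bin_average(x: np.ndarray, up: int, down: int, axis: int = -1) -> np.ndarray:
    """Decimate by averaging the input samples inside each output period.

    A *positive* linear map: nonnegative inputs stay nonnegative (an FIR
    polyphase filter rings negative on spiky power series), and averaging
    commutes exactly with any summation over frequencies or bands.
    """
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    n_out = int(np.ceil(n * up / down))
    edges = (np.arange(n_out) * down) // up
    sums = np.add.reduceat(x, edges, axis=-1)
    counts = np.diff(np.append(edges, n))
    return np.moveaxis(sums / counts, -1, axis)


def _output_times(t0_ms: float, n_in: int, fs_in: float, fs_out: float) -> np.ndarray:
    # output sample k averages the input over [k, k+1) / fs_out and carries
    # the left-edge time stamp
    up, down = _resample_factors(fs_in, fs_out)
    n_out = int(np.ceil(n_in * up / down))
    return t0_ms + np.arange(n_out) * 1000.0 / fs_out


def morlet_transform(
    epochs: EpochSet,
    freqs: np.ndarray | None = None,
    n_cycles: float = 5.0,
    fs_out: float = 50.25,
    crop_ms: tuple[float, float] = (0.0, 2000.0),
    keep_complex: bool = False,
) -> TimeFrequencyPower:
    """Morlet wavelet power, cropped to the analysis interval, at ``fs_out``.

    Power is the squared magnitude of the complex wavelet coefficients.
    Convolution runs over the full (padded) epoch so resampling edge
    artifacts stay outside the cropped interval; the crop then discards
    wavelet edge effects provided the epoch padding covers the half-width
    of the widest (lowest-frequency) wavelet.
    """
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= epochs.fs / 2):
        raise ValueError("analysis frequencies must lie in (0, fs/2)")
    widest = morlet_kernel(freqs.min(), n_cycles, epochs.fs)
    if widest.size > epochs.n_samples:
        raise ValueError(
            "epoch too short for the widest wavelet: need at least "
            f"{widest.size / epochs.fs:.3f} s, got {epochs.n_samples / epochs.fs:.3f} s"
        )

    times_out = _output_times(epochs.t0_ms, epochs.n_samples, epochs.fs, fs_out)
    keep = (times_out >= crop_ms[0]) & (times_out < crop_ms[1])
    up, down = _resample_factors(epochs.fs, fs_out)

    n_keep = int(keep.sum())
    power = np.empty(
        (epochs.n_trials, epochs.n_channels, freqs.size, n_keep), dtype=np.float64
    )
    coefs = (
        np.empty_like(power, dtype=np.complex128) if keep_complex else None
    )
    flat = epochs.data.reshape(-1, epochs.n_samples)
    for fi, f in enumerate(freqs):
        kernel = morlet_kernel(f, n_cycles, epochs.fs)
        conv = _sig.fftconvolve(flat, kernel[None, :], mode="same", axes=1)
        pw = _bin_average(np.abs(conv) ** 2, up, down, axis=1)
        power[:, :, fi, :] = pw[:, keep].reshape(
            epochs.n_trials, epochs.n_channels, n_keep
        )
        if coefs is not None:
            cf = _bin_average(conv, up, down, axis=1)
            coefs[:, :, fi, :] = cf[:, keep].reshape(
                epochs.n_trials, epochs.n_channels, n_keep
            )
    return TimeFrequencyPower(
        power=power,
        freqs_hz=freqs,
        fs_out=fs_out,
        times_ms=times_out[keep],
        coefs=coefs,
    )


def band_freq_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return (freqs >= lo) & (freqs <= hi)


def aggregate_band_power(
    tfr: TimeFrequencyPower,
    bands: Mapping[str, tuple[float, float]] | None = None,
    agg: str = "sum",
    channel_names: Sequence[str] | None = None,
) -> BandPowerTensor:
    """Collapse the frequency axis into named bands (sum by default)."""
    if bands is None:
        bands = DEFAULT_BANDS
    if agg not in ("sum", "mean"):
        raise ValueError("agg must be 'sum' or 'mean'")
    chunks = []
    for name, (lo, hi) in bands.items():
        mask = band_freq_mask(tfr.freqs_hz, (lo, hi))
        if not mask.any():
            raise ValueError(f"band {name!r} [{lo}, {hi}] contains no grid frequency")
        reducer = np.sum if agg == "sum" else np.mean
        chunks.append(reducer(tfr.power[:, :, mask, :], axis=2))
    bp = np.stack(chunks, axis=2)
    n_ch = bp.shape[1]
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]
    return BandPowerTensor(
        bp=bp,
        bands=dict(bands),
        fs_out=tfr.fs_out,
        times_ms=tfr.times_ms,
        channel_names=list(channel_names),
        normalized=False,
    )


def band_power_from_epochs(
    epochs: EpochSet,
    bands: Mapping[str, tuple[float, float]] | None = None,
    freqs: np.ndarray | None = None,
    n_cycles: float = 5.0,
    fs_out: float = 50.25,
    crop_ms: tuple[float, float] = (0.0, 2000.0),
    agg: str = "sum",
) -> BandPowerTensor:
    """Memory-lean epochs -> band power: accumulates per-frequency power
    into band slots instead of materializing the full trials x channels x
    frequencies x time tensor.  Numerically identical to
    ``aggregate_band_power(morlet_transform(...))`` because band summation
    commutes with the linear resampler.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= epochs.fs / 2):
        raise ValueError("analysis frequencies must lie in (0, fs/2)")
    widest = morlet_kernel(freqs.min(), n_cycles, epochs.fs)
    if widest.size > epochs.n_samples:
        raise ValueError(
            "epoch too short for the widest wavelet: need at least "
            f"{widest.size / epochs.fs:.3f} s"
        )
    masks = {}
    for name, (lo, hi) in bands.items():
        m = band_freq_mask(freqs, (lo, hi))
        if not m.any():
            raise ValueError(f"band {name!r} [{lo}, {hi}] contains no grid frequency")
        masks[name] = m

    n_s = epochs.n_samples
    flat = epochs.data.reshape(-1, n_s)
    kernels = [morlet_kernel(f, n_cycles, epochs.fs) for f in freqs]
    max_len = max(k.size for k in kernels)
    nfft = next_fast_len(n_s + max_len - 1)
    # one shared real forward transform; per frequency two real inverse
    # transforms (kernel real/imag parts), chunked for cache locality
    D = rfft(flat, nfft, axis=1)
    acc = np.zeros((len(bands), flat.shape[0], n_s))
    chunk = max(1, int(2**25 // max(nfft, 1)))
    for fi, f in enumerate(freqs):
        band_slots = [bi for bi, name in enumerate(bands) if masks[name][fi]]
        if not band_slots:
            continue
        kernel = kernels[fi]
        Kr = rfft(kernel.real, nfft)
        Ki = rfft(kernel.imag, nfft)
        start = (kernel.size - 1) // 2  # 'same' alignment
        for i in range(0, flat.shape[0], chunk):
            Dc = D[i : i + chunk]
            cr = irfft(Dc * Kr[None, :], nfft, axis=1)[:, start : start + n_s]
            ci = irfft(Dc * Ki[None, :], nfft, axis=1)[:, start : start + n_s]
            pw = cr**2 + ci**2
            for bi in band_slots:
                acc[bi, i : i + chunk] += pw
    if agg == "mean":
        for bi, name in enumerate(bands):
            acc[bi] /= masks[name].sum()
    elif agg != "sum":
        raise ValueError("agg must be 'sum' or 'mean'")

    up, down = _resample_factors(epochs.fs, fs_out)
    times_out = _output_times(epochs.t0_ms, n_s, epochs.fs, fs_out)
    keep = (times_out >= crop_ms[0]) & (times_out < crop_ms[1])
    res = _bin_average(acc, up, down, axis=2)[:, :, keep]
    bp = res.reshape(len(bands), epochs.n_trials, epochs.n_channels, -1)
    bp = np.moveaxis(bp, 0, 2)
    return BandPowerTensor(
        bp=np.ascontiguousarray(bp),
        bands=dict(bands),
        fs_out=fs_out,
        times_ms=times_out[keep],
        channel_names=list(epochs.channel_names),
        normalized=False,
    )


def normalize_band_power(
    bp: BandPowerTensor,
    pool: np.ndarray | None = None,
    stats: Mapping[str, tuple[float, float]] | None = None,
) -> BandPowerTensor:
    """Z-score each band over (pool trials x channels x time).

    ``stats`` overrides the pool computation so held-out trials can be
    transformed with training statistics.
    """
    if stats is None:
        idx = np.arange(bp.n_trials) if pool is None else np.asarray(pool)
        if idx.size == 0:
            raise ValueError("normalization pool is empty")
        stats = {}
        for bi, name in enumerate(bp.band_names):
            vals = bp.bp[idx, :, bi, :]
            mu = float(vals.mean())
            sd = float(vals.std(ddof=0))
            stats[name] = (mu, sd)
    out = np.empty_like(bp.bp)
    for bi, name in enumerate(bp.band_names):
        mu, sd = stats[name]
        if sd <= 0:
            raise ValueError(f"band {name!r} has zero variance over the pool")
        out[:, :, bi, :] = (bp.bp[:, :, bi, :] - mu) / sd
    return replace(bp, bp=out, normalized=True, norm_stats=dict(stats))


def average_regions(bp: BandPowerTensor, rmap: RegionMap) -> BandPowerTensor:
    """Collapse the channel axis to the 4 regions (unweighted means)."""
    idx = rmap.indices(bp.channel_names)
    series = []
    for region in REGION_ORDER:
        members = idx[region]
        if not members:
            raise ValueError(f"region {region!r} has no member channels")
        series.append(bp.bp[:, members, :, :].mean(axis=1))
    out = np.stack(series, axis=1)
    return replace(
        bp, bp=out, channel_names=list(REGION_ORDER), norm_stats=dict(bp.norm_stats)
    )
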