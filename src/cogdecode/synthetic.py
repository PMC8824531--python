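"""Synthetic labeled epoch sets with known ground truth.

Each trial is 1/f-shaped Gaussian background noise plus band-limited
oscillations (random frequency within the band and random phase per
trial).  Class-dependent effects either scale an oscillation's amplitude
inside a chosen channel subset and time window, or couple the oscillator
phase across two channel groups with a jitter that controls the attainable
phase-locking value.

The generator doubles as the calibration oracle: for a single
amplitude-type effect, ``analytic_bayes_accuracy`` estimates the Bayes
accuracy of the ideal univariate threshold rule on the effect cell's
mean-band-power feature from a large Monte-Carlo sample of the feature
distribution itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .signal_model import (
    DEFAULT_BANDS,
    DEFAULT_FREQS,
    EpochSet,
    band_freq_mask,
    default_montage_32,
    make_window_grid,
    morlet_kernel,
)

__all__ = [
    "Oscillation",
    "AmplitudeEffect",
    "PhaseCouplingEffect",
    "SyntheticSpec",
    "generate_epochs",
    "analytic_bayes_accuracy",
]


@dataclass
class Oscillation:
    center_hz: float
    bandwidth_hz: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("oscillation amplitude must be positive")


@dataclass
class AmplitudeEffect:
    """Multiply one oscillation's amplitude for one class, confined to a
    channel subset and a time window (ms, stimulus-relative)."""

    label: int
    osc_index: int
    channels: tuple[str, ...]
    window_ms: tuple[float, float]
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("amplitude factor must be positive")


@dataclass
class PhaseCouplingEffect:
    """Share the oscillator phase across two channel groups for one class;
    per-channel Gaussian phase jitter (rad) sets the attainable synchrony."""

    label: int
    osc_index: int
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    window_ms: tuple[float, float]
    jitter_sd: float = 0.2


@dataclass
class SyntheticSpec:
    n_trials: dict[int, int]
    channel_names: list[str] = field(default_factory=default_montage_32)
    fs: float = 256.0
    epoch_ms: tuple[float, float] = (-1000.0, 3000.0)
    background_exponent: float = 1.0
    background_amplitude: float = 1.0
    oscillations: list[Oscillation] = field(
        default_factory=lambda: [Oscillation(10.0, 2.0, 1.0)]
    )
    effects: list[AmplitudeEffect | PhaseCouplingEffect] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_trials or any(n < 1 for n in self.n_trials.values()):
            raise ValueError("every class needs at least one trial")
        if self.background_amplitude <= 0:
            raise ValueError("background amplitude must be positive")
        lo, hi = self.epoch_ms
        for e in self.effects:
            a, b = e.window_ms
            if a < lo or b > hi or a >= b:
                raise ValueError(f"effect window {e.window_ms} outside epoch")
            if e.osc_index >= len(self.oscillations):
                raise ValueError("effect references a missing oscillation")

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_ms[1] - self.epoch_ms[0]) / 1000.0 * self.fs))

    def times_ms(self) -> np.ndarray:
        return self.epoch_ms[0] + np.arange(self.n_samples) * 1000.0 / self.fs

    def to_dict(self) -> dict:
        return {
            "n_trials": {int(k): int(v) for k, v in self.n_trials.items()},
            "channel_names": list(self.channel_names),
            "fs": self.fs,
            "epoch_ms": list(self.epoch_ms),
            "background_exponent": self.background_exponent,
            "background_amplitude": self.background_amplitude,
            "oscillations": [o.__dict__ for o in self.oscillations],
            "effects": [
                {"type": type(e).__name__, **{
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in e.__dict__.items()
                }}
                for e in self.effects
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["n_trials"] = {int(k): int(v) for k, v in d["n_trials"].items()}
        if "epoch_ms" in d:
            d["epoch_ms"] = tuple(d["epoch_ms"])
        if "oscillations" in d:
            d["oscillations"] = [Oscillation(**o) for o in d["oscillations"]]
        effects = []
        for e in d.get("effects", []):
            e = dict(e)
            kind = e.pop("type")
            for key in ("channels", "group_a", "group_b", "window_ms"):
                if key in e:
                    e[key] = tuple(e[key])
            effects.append(
                AmplitudeEffect(**e) if kind == "AmplitudeEffect"
                else PhaseCouplingEffect(**e)
            )
        d["effects"] = effects
        return cls(**d)


def _one_over_f(rng: np.random.Generator, n: int, fs: float,
                exponent: float, amplitude: float, size: tuple) -> np.ndarray:
    """Gaussian noise with power spectral density ~ f^-exponent, unit-free
    amplitude = output standard deviation."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal(size + (n,))
    spec = np.fft.rfft(white, axis=-1) * shape
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return amplitude * x / sd


def _band_of(center_hz: float) -> str | None:
    for name, (lo, hi) in DEFAULT_BANDS.items():
        if lo <= center_hz <= hi:
            return name
    return None


def generate_epochs(spec: SyntheticSpec) -> tuple[EpochSet, list[dict]]:
    """Generate the epoch set plus the list of truly affected cells.

    Ground-truth cells are family-agnostic: each entry names the band,
    affected channels, effect window, and the default-grid window indices
    overlapping it.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.channel_names)
    ch_index = {c: i for i, c in enumerate(names)}
    n_ch, n_s = len(names), spec.n_samples
    t = spec.times_ms() / 1000.0  # seconds relative to stimulus onset
    labels = np.concatenate(
        [np.full(n, lab) for lab, n in sorted(spec.n_trials.items())]
    )
    n_trials = len(labels)
    data = _one_over_f(
        rng, n_s, spec.fs, spec.background_exponent,
        spec.background_amplitude, (n_trials, n_ch),
    )

    for oi, osc in enumerate(spec.oscillations):
        f_trial = osc.center_hz + (
            rng.uniform(-0.5, 0.5, n_trials) * osc.bandwidth_hz
        )
        base_phase = rng.uniform(0, 2 * np.pi, (n_trials, n_ch))
        amp = np.full((n_trials, n_ch, n_s), osc.amplitude)
        phase = base_phase[:, :, None]
        effs = [e for e in spec.effects if e.osc_index == oi]
        if any(isinstance(e, PhaseCouplingEffect) for e in effs):
            phase = np.broadcast_to(phase, (n_trials, n_ch, n_s)).copy()

        for eff in effs:
            trial_idx = np.flatnonzero(labels == eff.label)
            w = (t * 1000.0 >= eff.window_ms[0]) & (t * 1000.0 < eff.window_ms[1])
            w_idx = np.flatnonzero(w)
            if isinstance(eff, AmplitudeEffect):
                chans = [ch_index[c] for c in eff.channels]
                amp[np.ix_(trial_idx, chans, w_idx)] *= eff.factor
            else:
                shared = rng.uniform(0, 2 * np.pi, len(trial_idx))
                for group in (eff.group_a, eff.group_b):
                    for c in group:
                        ci = ch_index[c]
                        jit = rng.normal(0, eff.jitter_sd, len(trial_idx))
                        coupled = shared + jit
                        phase[np.ix_(trial_idx, [ci], w_idx)] = coupled[
                            :, None, None
                        ]
        carrier = np.cos(
            2 * np.pi * f_trial[:, None, None] * t[None, None, :] + phase
        )
        data += amp * carrier

    epochs = EpochSet(
        data=data, labels=labels, fs=spec.fs,
        channel_names=names, t0_ms=spec.epoch_ms[0],
    )

    grid = make_window_grid(0.0, 2000.0, 400.0, 200.0)
    truth = []
    for eff in spec.effects:
        band = _band_of(spec.oscillations[eff.osc_index].center_hz)
        overlap = [
            wi for wi, (a, b) in enumerate(grid.windows)
            if a < eff.window_ms[1] and b > eff.window_ms[0]
        ]
        chans = (
            list(eff.channels) if isinstance(eff, AmplitudeEffect)
            else list(eff.group_a) + list(eff.group_b)
        )
        truth.append(
            {
                "label": eff.label,
                "band": band,
                "channels": chans,
                "window_ms": tuple(eff.window_ms),
                "grid_windows": overlap,
                "kind": type(eff).__name__,
            }
        )
    return epochs, truth


def _mean_band_power_feature(
    spec: SyntheticSpec,
    eff: AmplitudeEffect,
    apply_effect: bool,
    n_draws: int,
    rng: np.random.Generator,
    fs_out: float = 50.25,
    batch: int = 2048,
) -> np.ndarray:
    """Monte-Carlo draws of the effect cell's mean band-power feature for a
    single channel, with or without the class effect applied."""
    osc = spec.oscillations[eff.osc_index]
    band_name = _band_of(osc.center_hz)
    if band_name is None:
        raise ValueError("effect oscillation lies outside every band")
    freqs = DEFAULT_FREQS[band_freq_mask(DEFAULT_FREQS, DEFAULT_BANDS[band_name])]
    n_s = spec.n_samples
    t = spec.times_ms() / 1000.0
    w_mask = (t * 1000.0 >= eff.window_ms[0]) & (t * 1000.0 < eff.window_ms[1])

    kernels = [morlet_kernel(f, 5.0, spec.fs) for f in freqs]
    out = np.empty(n_draws)
    done = 0
    while done < n_draws:
        b = min(batch, n_draws - done)
        x = _one_over_f(
            rng, n_s, spec.fs, spec.background_exponent,
            spec.background_amplitude, (b,),
        )
        f_trial = osc.center_hz + rng.uniform(-0.5, 0.5, b) * osc.bandwidth_hz
        phase = rng.uniform(0, 2 * np.pi, b)
        amp = np.full((b, n_s), osc.amplitude)
        if apply_effect:
            amp[:, w_mask] *= eff.factor
        x = x + amp * np.cos(
            2 * np.pi * f_trial[:, None] * t[None, :] + phase[:, None]
        )
        power = np.zeros((b, n_s))
        for k in kernels:
            conv = _sig.fftconvolve(x, k[None, :], mode="same", axes=1)
            power += np.abs(conv) ** 2
        # mean over the effect window of the band-power series; the feature
        # pipeline's resampling and z-scoring are monotone/affine maps of
        # this quantity, so threshold-rule accuracy is unchanged
        out[done : done + b] = power[:, w_mask].mean(axis=1)
        done += b
    return out


def _best_threshold_accuracy(x0: np.ndarray, x1: np.ndarray) -> float:
    """Balanced accuracy of the best single-threshold rule (either sign)."""
    both = np.concatenate([x0, x1])
    cand = np.quantile(both, np.linspace(0.0, 1.0, 2001))
    s0 = np.sort(x0)
    s1 = np.sort(x1)
    # P(x0 <= t) and P(x1 > t) for every candidate threshold
    p0 = np.searchsorted(s0, cand, side="right") / len(s0)
    p1 = 1.0 - np.searchsorted(s1, cand, side="right") / len(s1)
    acc = 0.5 * (p0 + p1)
    return float(max(acc.max(), (1.0 - acc).max()))


def analytic_bayes_accuracy(
    spec: SyntheticSpec,
    feature: str = "mean",
    n_draws: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Bayes accuracy of the ideal univariate threshold rule on the effect
    cell's mean-band-power feature, with its Monte-Carlo standard error.

    Requires a spec with exactly one amplitude-type effect (no closed form
    exists for multi-effect specs).  With no effect at all the answer is
    0.5 by exchangeability and is returned without simulation.
    """
    if feature != "mean":
        raise ValueError("only the mean-band-power feature is supported")
    amp_effects = [e for e in spec.effects if isinstance(e, AmplitudeEffect)]
    if len(spec.effects) == 0:
        return 0.5, 0.0
    if len(spec.effects) > 1 or not amp_effects:
        raise ValueError(
            "analytic accuracy requires exactly one amplitude-type effect"
        )
    eff = amp_effects[0]
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    x1 = _mean_band_power_feature(spec, eff, True, n_draws, rng)
    x0 = _mean_band_power_feature(spec, eff, False, n_draws, rng)
    acc = _best_threshold_accuracy(x0, x1)
    se = float(np.sqrt(acc * (1 - acc) * (1.0 / len(x0) + 1.0 / len(x1))))
    return acc, se
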