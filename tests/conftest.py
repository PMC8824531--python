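import numpy as np
import pytest

from cogdecode.signal_model import BandPowerTensor, EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bp(
    values: np.ndarray,
    fs_out: float = 50.25,
    t0_ms: float = 0.0,
    bands: dict | None = None,
    channel_names: list[str] | None = None,
    normalized: bool = True,
) -> BandPowerTensor:
    """Wrap a (trials, channels, bands, time) array as a BandPowerTensor."""
    values = np.asarray(values, dtype=float)
    n_t = values.shape[-1]
    if bands is None:
        bands = {f"b{i}": (float(i), float(i) + 1) for i in range(values.shape[2])}
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(values.shape[1])]
    return BandPowerTensor(
        bp=values,
        bands=bands,
        fs_out=fs_out,
        times_ms=t0_ms + np.arange(n_t) * 1000.0 / fs_out,
        channel_names=channel_names,
        normalized=normalized,
    )


def exact_moment_gaussian(
    rng: np.random.Generator, n: int, mean: np.ndarray, cov: np.ndarray
) -> np.ndarray:
    """Sample with *exact* sample mean and sample covariance (ddof=1)."""
    mean = np.asarray(mean, dtype=float)
    d = mean.size
    x = rng.standard_normal((n, d))
    x -= x.mean(axis=0)
    c = np.cov(x, rowvar=False, ddof=1)
    c = np.atleast_2d(c)
    l_emp = np.linalg.cholesky(c)
    l_tgt = np.linalg.cholesky(np.atleast_2d(cov))
    return mean + x @ np.linalg.inv(l_emp).T @ l_tgt.T


def tiny_epochs(
    rng: np.random.Generator,
    n_trials: int = 4,
    n_channels: int = 2,
    fs: float = 256.0,
    dur_s: float = 4.0,
    t0_ms: float = -1000.0,
) -> EpochSet:
    n_s = int(fs * dur_s)
    return EpochSet(
        data=rng.standard_normal((n_trials, n_channels, n_s)),
        labels=np.arange(n_trials) % 2,
        fs=fs,
        channel_names=[f"C{i}" for i in range(n_channels)],
        t0_ms=t0_ms,
    )
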