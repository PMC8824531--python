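import numpy as np
import pytest

import cogdecode.features as ft
from cogdecode.features import (
    FAMILY_ORDER,
    REGION_PAIRS,
    CSPModel,
    FeatureConfig,
    csp_eig,
    extract_all,
    extract_ar,
    extract_correlation,
    extract_csp_features,
    extract_entropy,
    extract_mean,
    extract_phase,
    extract_phase_sync,
    extract_variance,
    fit_csp,
    instantaneous_phase,
)
from cogdecode.signal_model import REGION_ORDER, make_window_grid
from cogdecode.synthetic import SyntheticSpec, generate_epochs

from conftest import make_bp

GRID = make_window_grid(0, 2000, 400, 200)
N_T = 101  # samples covering [0, 2000) at 50.25 Hz


def region_names():
    return list(REGION_ORDER)


# ---------------------------------------------------------------------------
# mean / variance / entropy


def test_mean_constant_power(rng):
    bp = make_bp(np.full((3, 2, 4, N_T), 2.5))
    X, desc = extract_mean(bp, GRID)
    np.testing.assert_allclose(X, 2.5)
    assert len(desc) == 2 * 9 * 4


def test_mean_default_config_column_count(rng):
    bp = make_bp(rng.random((2, 32, 4, N_T)))
    X, desc = extract_mean(bp, GRID)
    assert X.shape == (2, 1152)


def test_mean_matches_direct_oracle(rng):
    bp = make_bp(rng.random((3, 2, 4, N_T)))
    X, desc = extract_mean(bp, GRID)
    from cogdecode.signal_model import window_sample_indices

    slices = window_sample_indices(GRID, bp.times_ms, bp.fs_out)
    for j, d in enumerate(desc):
        ci = bp.channel_names.index(d.locus)
        bi = bp.band_names.index(d.band)
        expected = bp.bp[:, ci, bi, slices[d.window]].mean(axis=1)
        np.testing.assert_allclose(X[:, j], expected)


def test_variance_constant_zero():
    bp = make_bp(np.full((2, 1, 1, N_T), 3.0))
    X, _ = extract_variance(bp, GRID)
    np.testing.assert_allclose(X, 0.0)


def test_variance_two_point_closed_form():
    # window of exactly two samples {0, 2}: sample variance (n-1) = 2
    grid = make_window_grid(0, 100, 100, 100)
    vals = np.zeros((1, 1, 1, 2))
    vals[0, 0, 0] = [0.0, 2.0]
    bp = make_bp(vals, fs_out=20.0)
    X, _ = extract_variance(bp, grid)
    np.testing.assert_allclose(X, 2.0)


def test_variance_matches_two_pass_oracle(rng):
    bp = make_bp(rng.random((2, 2, 2, N_T)))
    X, desc = extract_variance(bp, GRID)
    from cogdecode.signal_model import window_sample_indices

    slices = window_sample_indices(GRID, bp.times_ms, bp.fs_out)
    d = desc[7]
    ci = bp.channel_names.index(d.locus)
    bi = bp.band_names.index(d.band)
    w = bp.bp[:, ci, bi, slices[d.window]]
    mu = w.mean(axis=1, keepdims=True)
    expected = ((w - mu) ** 2).sum(axis=1) / (w.shape[1] - 1)
    np.testing.assert_allclose(X[:, 7], expected)


def test_entropy_constant_is_zero():
    bp = make_bp(np.full((2, 1, 1, N_T), 1.7))
    X, _ = extract_entropy(bp, GRID)
    np.testing.assert_allclose(X, 0.0)


def test_entropy_uniform_four_bins_is_two_bits():
    # 20 samples spread evenly over 4 equally occupied bins
    vals = np.zeros((1, 1, 1, N_T))
    pattern = np.repeat([0.0, 1.0, 2.0, 3.0], 5)
    vals[0, 0, 0, :20] = pattern
    vals[0, 0, 0, 20:] = np.resize(pattern, N_T - 20)
    bp = make_bp(vals)
    X, _ = extract_entropy(bp, GRID, n_bins=4)
    np.testing.assert_allclose(X[0, 0], 2.0)


def test_entropy_matches_histogram_oracle(rng):
    bp = make_bp(rng.random((3, 2, 2, N_T)))
    n_bins = 5
    X, desc = extract_entropy(bp, GRID, n_bins=n_bins)
    from cogdecode.signal_model import window_sample_indices

    slices = window_sample_indices(GRID, bp.times_ms, bp.fs_out)
    for j in rng.choice(len(desc), 10, replace=False):
        d = desc[j]
        ci = bp.channel_names.index(d.locus)
        bi = bp.band_names.index(d.band)
        for t in range(3):
            w = bp.bp[t, ci, bi, slices[d.window]]
            counts, _ = np.histogram(w, bins=n_bins, range=(w.min(), w.max()))
            p = counts[counts > 0] / len(w)
            np.testing.assert_allclose(X[t, j], -(p * np.log2(p)).sum())


def test_entropy_range_invariant():
    with pytest.raises(ValueError):
        extract_entropy(make_bp(np.ones((1, 1, 1, N_T))), GRID, n_bins=1)


# ---------------------------------------------------------------------------
# correlation


def test_correlation_identical_series(rng):
    vals = np.tile(rng.random((1, 1, 2, N_T)), (2, 4, 1, 1))
    bp = make_bp(vals, channel_names=region_names())
    X, _ = extract_correlation(bp, GRID)
    np.testing.assert_allclose(X, 1.0)


def test_correlation_negated_series(rng):
    base = rng.random((2, 1, 1, N_T))
    vals = np.concatenate([base, -base, base, -base], axis=1)
    bp = make_bp(vals, channel_names=region_names())
    X, desc = extract_correlation(bp, GRID)
    for j, d in enumerate(desc):
        a, b = d.locus.split("~")
        sign = -1.0 if (region_names().index(a) + region_names().index(b)) % 2 else 1.0
        np.testing.assert_allclose(X[:, j], sign, atol=1e-12)


def test_correlation_matches_pearson_oracle(rng):
    bp = make_bp(rng.random((2, 4, 2, N_T)), channel_names=region_names())
    X, desc = extract_correlation(bp, GRID)
    from cogdecode.signal_model import window_sample_indices

    slices = window_sample_indices(GRID, bp.times_ms, bp.fs_out)
    for j, d in enumerate(desc):
        i1, i2 = (region_names().index(r) for r in d.locus.split("~"))
        bi = bp.band_names.index(d.band)
        for t in range(2):
            a = bp.bp[t, i1, bi, slices[d.window]]
            b = bp.bp[t, i2, bi, slices[d.window]]
            expected = np.corrcoef(a, b)[0, 1]
            np.testing.assert_allclose(X[t, j], expected, atol=1e-12)


def test_correlation_zero_variance_defaults_to_zero(rng):
    vals = rng.random((1, 4, 1, N_T))
    vals[0, 0] = 5.0  # flat series in every window
    bp = make_bp(vals, channel_names=region_names())
    with pytest.warns(UserWarning, match="zero-variance"):
        X, desc = extract_correlation(bp, GRID)
    for j, d in enumerate(desc):
        if "frontal-left" in d.locus:
            assert X[0, j] == 0.0


# ---------------------------------------------------------------------------
# phase and phase synchrony


def test_phase_constant_is_one():
    phases = np.full((2, 1, 1, N_T), 0.7)
    bp = make_bp(np.ones((2, 1, 1, N_T)))
    X, _ = extract_phase(bp, GRID, phases=phases)
    np.testing.assert_allclose(X, 1.0)


def test_phase_quadrature_cancels():
    phases = np.zeros((1, 1, 1, N_T))
    phases[0, 0, 0] = np.resize([0.0, np.pi / 2, np.pi, 3 * np.pi / 2], N_T)
    bp = make_bp(np.ones((1, 1, 1, N_T)))
    X, _ = extract_phase(bp, GRID, phases=phases)
    np.testing.assert_allclose(X, 0.0, atol=1e-12)


def test_phase_matches_complex_mean_oracle(rng):
    phases = rng.uniform(0, 2 * np.pi, (2, 2, 2, N_T))
    bp = make_bp(np.ones((2, 2, 2, N_T)))
    X, desc = extract_phase(bp, GRID, phases=phases)
    from cogdecode.signal_model import window_sample_indices

    slices = window_sample_indices(GRID, bp.times_ms, bp.fs_out)
    for j, d in enumerate(desc):
        ci = bp.channel_names.index(d.locus)
        bi = bp.band_names.index(d.band)
        expected = np.abs(
            np.exp(1j * phases[:, ci, bi, slices[d.window]]).mean(axis=1)
        )
        np.testing.assert_allclose(X[:, j], expected)
    assert np.all(X >= 0) and np.all(X <= 1)


def test_phase_sync_identical_series():
    phases = np.tile(np.linspace(0, 6, N_T), (1, 4, 1, 1))
    bp = make_bp(np.ones((1, 4, 1, N_T)), channel_names=region_names())
    X, _ = extract_phase_sync(bp, GRID, phases=phases)
    np.testing.assert_allclose(X, 1.0)


def test_phase_sync_quadrature_differences_cancel():
    phases = np.zeros((1, 4, 1, N_T))
    phases[0, 0, 0] = np.resize([0.0, np.pi / 2, np.pi, 3 * np.pi / 2], N_T)
    bp = make_bp(np.ones((1, 4, 1, N_T)), channel_names=region_names())
    X, desc = extract_phase_sync(bp, GRID, phases=phases)
    j = next(
        i for i, d in enumerate(desc)
        if d.locus == "frontal-left~frontal-right" and d.window == 0
    )
    np.testing.assert_allclose(X[0, j], 0.0, atol=1e-12)


def test_phase_sync_matches_plv_oracle(rng):
    phases = rng.uniform(0, 2 * np.pi, (2, 4, 2, N_T))
    bp = make_bp(np.ones((2, 4, 2, N_T)), channel_names=region_names())
    X, desc = extract_phase_sync(bp, GRID, phases=phases)
    from cogdecode.signal_model import window_sample_indices

    slices = window_sample_indices(GRID, bp.times_ms, bp.fs_out)
    for j, d in enumerate(desc):
        i1, i2 = (region_names().index(r) for r in d.locus.split("~"))
        bi = bp.band_names.index(d.band)
        diff = phases[:, i1, bi, slices[d.window]] - phases[:, i2, bi, slices[d.window]]
        np.testing.assert_allclose(X[:, j], np.abs(np.exp(1j * diff).mean(axis=1)))


def test_instantaneous_phase_scale_invariant(rng):
    bp = make_bp(rng.random((2, 2, 1, N_T)) + 1.0)
    bp2 = make_bp(bp.bp * 3.0 - 5.0)
    np.testing.assert_allclose(
        instantaneous_phase(bp), instantaneous_phase(bp2), atol=1e-9
    )


# ---------------------------------------------------------------------------
# AR


def test_ar_recovers_generator_coefficients(rng):
    alpha = np.array([0.6, -0.2, 0.0, 0.0])
    n = 4000
    x = np.zeros(n)
    noise = rng.normal(0, 0.01, n)
    for i in range(4, n):
        x[i] = alpha @ x[i - 4 : i][::-1] + noise[i]
    grid = make_window_grid(0, n, n, n)
    bp = make_bp(x[None, None, None, :], fs_out=1000.0)
    X, _ = extract_ar(bp, grid, order=4)
    np.testing.assert_allclose(X[0], alpha, atol=0.05)


def test_ar_zero_series_degeneracy():
    bp = make_bp(np.zeros((1, 1, 1, N_T)))
    with pytest.warns(UserWarning, match="rank-deficient"):
        X, _ = extract_ar(bp, GRID, order=4)
    np.testing.assert_allclose(X, 0.0)


def test_ar_matches_normal_equations_oracle(rng):
    bp = make_bp(rng.random((2, 4, 1, N_T)), channel_names=region_names())
    p = 4
    X, desc = extract_ar(bp, GRID, order=p)
    from cogdecode.signal_model import window_sample_indices

    slices = window_sample_indices(GRID, bp.times_ms, bp.fs_out)
    d = desc[0]
    assert d.coef == 1
    ri = region_names().index(d.locus)
    bi = bp.band_names.index(d.band)
    series = bp.bp[0, ri, bi, slices[d.window]]
    A = np.column_stack([series[p - i : len(series) - i] for i in range(1, p + 1)])
    y = series[p:]
    expected, *_ = np.linalg.lstsq(A, y, rcond=None)
    got = [X[0, j] for j, dj in enumerate(desc)
           if dj.locus == d.locus and dj.band == d.band and dj.window == d.window]
    np.testing.assert_allclose(got, expected, atol=1e-8)


def test_ar_window_too_short():
    grid = make_window_grid(0, 100, 100, 100)
    bp = make_bp(np.ones((1, 1, 1, 4)), fs_out=40.0)
    with pytest.raises(ValueError, match="AR"):
        extract_ar(bp, grid, order=4)


# ---------------------------------------------------------------------------
# CSP


def test_csp_diagonal_case():
    C1 = np.diag([2.0, 1.0])
    C2 = np.diag([1.0, 2.0])
    W, vals = csp_eig(C1, C2)
    # filters are the coordinate axes; variance ratios w'C1w / w'C2w = 2, 1/2
    ratios = [(w @ C1 @ w) / (w @ C2 @ w) for w in W.T]
    np.testing.assert_allclose(sorted(ratios), [0.5, 2.0])
    for w in W.T:
        assert np.isclose(np.abs(w[0]) * np.abs(w[1]), 0.0, atol=1e-12)


def test_csp_identical_distributions_no_separation(rng):
    A = rng.standard_normal((3, 3))
    C = A @ A.T + np.eye(3)
    _, vals = csp_eig(C, C)
    np.testing.assert_allclose(vals, 0.5, atol=1e-10)


def test_csp_matches_grid_search_oracle(rng):
    A1 = rng.standard_normal((3, 3))
    A2 = rng.standard_normal((3, 3))
    C1 = A1 @ A1.T + 0.1 * np.eye(3)
    C2 = A2 @ A2.T + 0.1 * np.eye(3)
    W, vals = csp_eig(C1, C2)
    # dense unit-vector grid search over the sphere
    th = np.linspace(0, np.pi, 120)
    ph = np.linspace(0, 2 * np.pi, 240, endpoint=False)
    T, P = np.meshgrid(th, ph, indexing="ij")
    U = np.stack(
        [np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1
    ).reshape(-1, 3)
    q = np.einsum("nd,de,ne->n", U, C1, U) / np.einsum(
        "nd,de,ne->n", U, C1 + C2, U
    )
    w_best = W[:, 0]
    rq = (w_best @ C1 @ w_best) / (w_best @ (C1 + C2) @ w_best)
    assert rq >= q.max() - 1e-3  # eigenvector attains the grid max
    w_worst = W[:, -1]
    rq_min = (w_worst @ C1 @ w_worst) / (w_worst @ (C1 + C2) @ w_worst)
    assert rq_min <= q.min() + 1e-3
    np.testing.assert_allclose(vals[0], rq)


def test_csp_simultaneous_diagonalization(rng):
    bp = make_bp(rng.random((12, 4, 2, N_T)))
    labels = np.repeat([0, 1], 6)
    model = fit_csp(bp, GRID, labels)
    for (bi, wi), W in model.filters.items():
        C1, C2 = model.covs[(bi, wi)]
        D1 = W.T @ C1 @ W
        D12 = W.T @ (C1 + C2) @ W
        assert np.abs(D1 - np.diag(np.diag(D1))).max() < 1e-8
        assert np.abs(D12 - np.diag(np.diag(D12))).max() < 1e-8


def test_csp_identity_filters_equal_variance(rng):
    bp = make_bp(rng.random((3, 4, 2, N_T)))
    model = CSPModel(
        filters={(bi, wi): np.eye(4) for bi in range(2) for wi in range(9)},
        class_pair=(0, 1),
        band_names=bp.band_names,
        n_windows=9,
    )
    Xc, dc = extract_csp_features(bp, GRID, model)
    Xv, dv = extract_variance(bp, GRID)
    np.testing.assert_allclose(Xc, Xv, atol=1e-12)


def test_csp_feature_count_and_projection_oracle(rng):
    bp = make_bp(rng.random((8, 32, 4, N_T)))
    labels = np.repeat([0, 1], 4)
    model = fit_csp(bp, GRID, labels)
    X, desc = extract_csp_features(bp, GRID, model)
    assert X.shape == (8, 1152)
    from cogdecode.signal_model import window_sample_indices

    slices = window_sample_indices(GRID, bp.times_ms, bp.fs_out)
    d = desc[40]
    bi = bp.band_names.index(d.band)
    W = model.filters[(bi, d.window)]
    k = int(d.locus.removeprefix("comp"))
    proj = W[:, k] @ bp.bp[0, :, bi, slices[d.window]].T @ np.eye(len(slices[d.window]))
    proj = (W[:, k][None, :] @ bp.bp[0, :, bi, :][:, slices[d.window]]).ravel()
    np.testing.assert_allclose(X[0, 40], proj.var(ddof=1))


def test_csp_requires_two_classes(rng):
    bp = make_bp(rng.random((6, 2, 1, N_T)))
    with pytest.raises(ValueError, match="2 classes"):
        fit_csp(bp, GRID, np.array([0, 1, 2, 0, 1, 2]))
    with pytest.raises(ValueError, match=">= 2 training trials"):
        fit_csp(bp, GRID, np.array([0, 1, 1, 1, 1, 1]))


# ---------------------------------------------------------------------------
# assembly


@pytest.fixture(scope="module")
def small_epochs():
    spec = SyntheticSpec(n_trials={0: 6, 1: 6}, seed=11)
    ep, _ = generate_epochs(spec)
    return ep


def test_full_default_configuration_yields_6768(small_epochs):
    fm = extract_all(small_epochs)
    assert fm.X.shape[1] == 6768
    counts = {f: len(fm.family_columns(f)) for f in FAMILY_ORDER}
    assert counts == {
        "mean": 1152, "variance": 1152, "entropy": 1152, "phase": 1152,
        "correlation": 216, "phase_sync": 216, "ar": 576, "csp": 1152,
    }


def test_single_family_column_count(small_epochs):
    fm = extract_all(small_epochs, FeatureConfig(families=("mean",)))
    assert fm.X.shape[1] == 1152


def test_descriptor_order_is_canonical(small_epochs):
    fm = extract_all(small_epochs, FeatureConfig(families=("mean", "csp")))
    fams = [d.family for d in fm.descriptors]
    assert fams == ["mean"] * 1152 + ["csp"] * 1152


def test_identical_trials_identical_rows():
    spec = SyntheticSpec(n_trials={0: 2, 1: 2}, seed=3)
    ep, _ = generate_epochs(spec)
    ep.data[1] = ep.data[0]
    cfg = FeatureConfig(families=("mean", "variance", "entropy", "phase"))
    fm = extract_all(ep, cfg)
    np.testing.assert_allclose(fm.X[0], fm.X[1])


def test_trial_permutation_permutes_rows():
    spec = SyntheticSpec(n_trials={0: 4, 1: 4}, seed=5)
    ep, _ = generate_epochs(spec)
    cfg = FeatureConfig(
        families=("mean", "variance", "entropy", "phase", "correlation",
                  "phase_sync", "ar"),
        normalization_pool="all",
    )
    fm = extract_all(ep, cfg)
    perm = np.array([3, 1, 0, 2, 7, 6, 5, 4])
    ep2 = type(ep)(
        data=ep.data[perm], labels=ep.labels[perm], fs=ep.fs,
        channel_names=ep.channel_names, t0_ms=ep.t0_ms,
    )
    fm2 = extract_all(ep2, cfg)
    np.testing.assert_allclose(fm2.X, fm.X[perm], atol=1e-10)


def test_feature_values_bounded(small_epochs):
    fm = extract_all(small_epochs)
    assert np.all(np.isfinite(fm.X))
    for fam, lo, hi in (("phase", 0, 1), ("phase_sync", 0, 1)):
        cols = fm.family_columns(fam)
        assert np.all(fm.X[:, cols] >= lo) and np.all(fm.X[:, cols] <= hi)
    ent = fm.family_columns("entropy")
    assert np.all(fm.X[:, ent] <= np.log2(5) + 1e-12)
    assert np.all(fm.X[:, ent] >= 0)


def test_unknown_family_rejected():
    with pytest.raises(ValueError, match="unknown feature families"):
        FeatureConfig(families=("mean", "wavelets"))
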