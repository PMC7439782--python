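"""DE/PSD/Lyapunov features, grid mapping, and normalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from eegid import features
from eegid.features import (
    ElectrodeMap,
    EmbeddingSpec,
    compute_feature_tensor,
    de_values,
    differential_entropy,
    grid_to_vector,
    map_to_grid,
    max_lyapunov,
    normalize_features,
    psd_feature,
    psd_periodogram,
)

RNG = np.random.default_rng(42)


# ---------------------------------------------------------------------------
# differential entropy


def test_de_closed_form_reference_points():
    w = RNG.standard_normal(500)
    w = (w - w.mean()) / w.std()          # sample variance exactly 1
    assert differential_entropy(w).h == pytest.approx(0.5 * np.log(2 * np.pi * np.e), abs=1e-10)
    w2 = w / np.sqrt(2 * np.pi * np.e)    # sigma^2 = 1/(2 pi e) -> h = 0
    assert differential_entropy(w2).h == pytest.approx(0.0, abs=1e-10)


@given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 100))
def test_de_scale_law(scale, seed):
    """h(a X) = h(X) + ln a for any a > 0."""
    x = np.random.default_rng(seed).standard_normal(256)
    h0 = differential_entropy(x).h
    h1 = differential_entropy(scale * x).h
    assert h1 == pytest.approx(h0 + np.log(scale), abs=1e-9)


def test_de_matches_nonparametric_estimator():
    draws = np.random.default_rng(1).normal(0.0, 2.0, 100_000)
    closed = differential_entropy(draws).h
    nonparam = stats.differential_entropy(draws, method="vasicek")
    assert abs(closed - nonparam) < 0.05


def test_de_zero_variance_is_floored_and_flagged():
    v = differential_entropy(np.full(100, 3.14))
    assert v.floored
    assert v.h == pytest.approx(0.5 * np.log(2 * np.pi * np.e * features.VAR_FLOOR))
    h, fl = de_values(np.zeros((2, 3, 100)))
    assert fl.all() and h.shape == (2, 3)


def test_de_rejects_degenerate_windows():
    with pytest.raises(ValueError):
        differential_entropy(np.array([1.0]))


# ---------------------------------------------------------------------------
# periodogram


def test_psd_direct_dft_equivalence():
    """The fast path must equal the textbook sum over n of x_n e^{-2 pi i f n / L}."""
    x = RNG.standard_normal(32)
    fs = 200.0
    freqs, psd = psd_periodogram(x, fs)
    L = len(x)
    for f_idx in range(L):
        direct = abs(sum(x[n] * np.exp(-2j * np.pi * f_idx * n / L) for n in range(L))) ** 2
        assert psd[f_idx] == pytest.approx(direct / (L * fs), rel=1e-9, abs=1e-12)


def test_psd_zero_signal_and_sinusoid_peak():
    _, p = psd_periodogram(np.zeros(100), 200.0)
    assert np.all(p == 0)
    t = np.arange(200) / 200.0
    freqs, p = psd_periodogram(np.sin(2 * np.pi * 10 * t), 200.0)
    half = p[:101]
    assert np.argmax(half) == 10      # 1 Hz bins: peak exactly at 10 Hz
    assert np.all(p >= 0)


def test_psd_parseval():
    x = RNG.standard_normal(1000)
    _, p = psd_periodogram(x, 200.0)
    energy = (x**2).sum()
    assert p.sum() * 200.0 == pytest.approx(energy, rel=1e-8)


def test_psd_feature_errors_on_empty():
    with pytest.raises(ValueError):
        psd_periodogram(np.array([]), 200.0)
    with pytest.raises(ValueError):
        psd_feature(np.empty((3, 0)), 200.0)


# ---------------------------------------------------------------------------
# maximum Lyapunov exponent


def _logistic(n, x0=0.123):
    out = np.empty(n)
    x = x0
    for i in range(n):
        x = 4.0 * x * (1.0 - x)
        out[i] = x
    return out


def _two_trajectory_slope(n_pairs=200, d0=1e-9, fit_steps=11):
    """Independent oracle: perturb a trajectory by d0, iterate both copies,
    fit the log-separation growth rate directly."""
    a = 0.3123
    slopes = []
    for _ in range(n_pairs):
        aa, bb = a, a + d0
        logs = []
        for _ in range(fit_steps + 2):
            aa = 4 * aa * (1 - aa)
            bb = 4 * bb * (1 - bb)
            d = abs(aa - bb)
            if d == 0:
                break
            logs.append(np.log(d))
        if len(logs) > fit_steps:
            slopes.append(np.polyfit(np.arange(fit_steps), logs[:fit_steps], 1)[0])
        a = 4 * a * (1 - a)
    return float(np.mean(slopes))


def test_lyapunov_recovers_logistic_map_rate():
    series = _logistic(10_000)
    res = max_lyapunov(series, EmbeddingSpec(D=2, tau=1, horizon=7))
    oracle = _two_trajectory_slope()
    assert res.lam == pytest.approx(np.log(2), rel=0.10)
    assert res.lam == pytest.approx(oracle, rel=0.10)


def test_lyapunov_near_zero_for_periodic_signal():
    t = np.arange(5000)
    res = max_lyapunov(np.sin(2 * np.pi * 5 * t / 200), EmbeddingSpec(D=10, tau=4, horizon=10))
    assert res.lam <= 0.05


def test_lyapunov_rejects_bad_input():
    with pytest.raises(ValueError):
        max_lyapunov(np.full(2000, 1.0))
    with pytest.raises(ValueError):
        max_lyapunov(_logistic(30), EmbeddingSpec(D=10, tau=4, horizon=10))
    with pytest.raises(ValueError):
        EmbeddingSpec(D=1, tau=1)


# ---------------------------------------------------------------------------
# electrode grid


def test_default_map_counts(emap):
    assert emap.n_named == 62
    assert emap.n_empty == 19
    assert len(set(emap.channel_names)) == 62


def test_mapping_preserves_values_and_zeros(emap):
    vals = np.arange(1.0, 63.0)
    grid = map_to_grid(vals, emap)
    assert grid.shape == (9, 9)
    assert set(grid[grid != 0]) == set(vals)
    assert (grid == 0).sum() == 19
    assert np.all(map_to_grid(np.zeros(62), emap) == 0)


def test_map_unmap_round_trip(emap):
    vals = RNG.standard_normal((3, 62))
    np.testing.assert_array_equal(grid_to_vector(map_to_grid(vals, emap), emap), vals)


def test_map_rejects_wrong_length(emap):
    with pytest.raises(ValueError):
        map_to_grid(np.zeros(60), emap)


def test_map_json_round_trip(tmp_path, emap):
    emap.to_json(tmp_path / "m.json")
    again = ElectrodeMap.from_json(tmp_path / "m.json")
    assert again.grid == emap.grid
    assert again.channel_names == emap.channel_names


def test_duplicate_channel_rejected(emap):
    grid = [list(r) for r in emap.grid]
    grid[0][0] = "FP1"  # already placed elsewhere
    with pytest.raises(ValueError):
        ElectrodeMap(grid)


# ---------------------------------------------------------------------------
# feature tensors


def test_feature_tensor_shapes(emap):
    banded = RNG.standard_normal((5, 4, 62, 200))
    assert compute_feature_tensor(banded, emap, "de").shape == (5, 4, 9, 9)
    assert compute_feature_tensor(banded[:, :1], emap, "de").shape == (5, 1, 9, 9)
    assert compute_feature_tensor(banded, emap, "psd", fs=200).shape == (5, 4, 9, 9)
    with pytest.raises(ValueError):
        compute_feature_tensor(banded, emap, "wavelet")
    with pytest.raises(ValueError):
        compute_feature_tensor(banded[:, :, :60], emap, "de")


def test_zero_clip_gives_floor_entropy_on_named_cells(emap):
    out = compute_feature_tensor(np.zeros((5, 2, 62, 200)), emap, "de")
    floor = 0.5 * np.log(2 * np.pi * np.e * features.VAR_FLOOR)
    named = grid_to_vector(out, emap)
    assert np.all(named == floor)
    assert (out == 0).sum() == 5 * 2 * 19


# ---------------------------------------------------------------------------
# normalization


def test_normalization_standardizes_each_position(emap):
    x = RNG.standard_normal((40, 5, 4, 9, 9)) * 3.0 + 1.5
    out, flagged = normalize_features(x)
    assert not flagged.any()
    np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-10)


def test_normalization_idempotent_and_stable(emap):
    x = RNG.standard_normal((30, 5, 4, 9, 9))
    once, _ = normalize_features(x)
    twice, _ = normalize_features(once)
    np.testing.assert_allclose(twice, once, atol=1e-10)


def test_constant_positions_flagged_and_zeroed():
    x = RNG.standard_normal((20, 5, 4, 9, 9))
    x[:, 0, 0, 0, 0] = 7.7   # constant across clips
    out, flagged = normalize_features(x)
    assert flagged[0, 0, 0, 0]
    assert np.all(out[:, 0, 0, 0, 0] == 0)


def test_channel_mode_standardizes_across_grid(emap):
    x = RNG.standard_normal((6, 5, 4, 9, 9))
    x = map_to_grid(grid_to_vector(x, emap), emap)  # zero the empty cells
    out, _ = normalize_features(x, mode="channel", emap=emap)
    named = grid_to_vector(out, emap)
    np.testing.assert_allclose(named.mean(axis=-1), 0.0, atol=1e-10)
    np.testing.assert_allclose(named.std(axis=-1), 1.0, atol=1e-10)
    empties = out.copy()
    empties[..., emap._rows, emap._cols] = 0
    assert np.all(empties == 0)
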