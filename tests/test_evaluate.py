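"""Rank-1 / EER metrics against brute-force oracles; protocol bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eegid.evaluate import (
    condition_transfer,
    cross_condition,
    eer,
    far_frr_curve,
    interval_protocol,
    kfold_protocol,
    rank1,
)
from eegid.model import ModelSpec, TrainConfig, build_model


# ---------------------------------------------------------------------------
# rank-1


def test_rank1_direct_counts():
    probs = np.array([[0.9, 0.1], [0.2, 0.8], [0.6, 0.4], [0.3, 0.7]])
    assert rank1(probs, np.array([0, 1, 0, 0])) == 0.75
    assert rank1(probs, probs.argmax(axis=1)) == 1.0
    assert rank1(probs, 1 - probs.argmax(axis=1)) == 0.0
    with pytest.raises(ValueError):
        rank1(np.empty((0, 2)), np.empty(0, dtype=int))


# ---------------------------------------------------------------------------
# EER


def _brute_eer(genuine, impostor):
    """Exhaustive enumeration oracle: scan every candidate threshold with
    explicit comparisons and interpolate the crossing linearly."""
    ts = np.unique(np.concatenate([genuine, impostor]))
    ts = np.concatenate([[ts[0] - 1.0], ts, [ts[-1] + 1.0]])
    prev_far = prev_frr = None
    for t in ts:
        far = sum(1 for s in impostor if s >= t) / len(impostor)
        frr = sum(1 for s in genuine if s < t) / len(genuine)
        if far <= frr:
            if prev_far is None or far == frr:
                return far
            d0, d1 = prev_far - prev_frr, far - frr
            a = d0 / (d0 - d1)
            return prev_far + a * (far - prev_far)
        prev_far, prev_frr = far, frr
    raise AssertionError("no crossing found")


def _scores_to_probs(genuine, impostor):
    """Pack one genuine/impostor score pair per row of a 2-class score set."""
    return np.column_stack([genuine, impostor]), np.zeros(len(genuine), dtype=int)


def test_eer_perfect_separation_is_zero():
    probs, y = _scores_to_probs([0.9, 0.8], [0.1, 0.2])
    assert eer(probs, y) == 0.0


def test_eer_textbook_crossing():
    probs, y = _scores_to_probs([0.8, 0.4], [0.6, 0.2])
    assert eer(probs, y) == pytest.approx(0.5)
    assert eer(probs, y) == pytest.approx(_brute_eer([0.8, 0.4], [0.6, 0.2]))


def test_eer_identical_distributions_is_half():
    rng = np.random.default_rng(2)
    n = 10_000
    probs = rng.random((n, 2))
    y = rng.integers(0, 2, n)
    assert eer(probs, y) == pytest.approx(0.5, abs=0.02)


def test_eer_matches_brute_force_on_random_sets():
    rng = np.random.default_rng(0)
    for trial in range(5):
        n = 200
        probs = rng.random((n, 4))
        y = rng.integers(0, 4, n)
        genuine = probs[np.arange(n), y]
        mask = np.ones_like(probs, bool)
        mask[np.arange(n), y] = False
        assert eer(probs, y) == pytest.approx(_brute_eer(genuine, probs[mask]), abs=1e-12)


def test_eer_agrees_with_roc_crossing():
    """Independent route: the EER is where the ROC meets FPR = 1 - TPR."""
    from sklearn.metrics import roc_curve
    rng = np.random.default_rng(1)
    n = 2000
    probs = np.column_stack([rng.normal(0.6, 0.2, n), rng.normal(0.4, 0.2, n)])
    y = np.zeros(n, dtype=int)
    labels = np.concatenate([np.ones(n), np.zeros(n)])
    scores = np.concatenate([probs[:, 0], probs[:, 1]])
    fpr, tpr, _ = roc_curve(labels, scores)
    sk_eer = fpr[np.argmin(np.abs(fpr - (1 - tpr)))]
    assert eer(probs, y) == pytest.approx(sk_eer, abs=2.0 / n)


@given(seed=st.integers(0, 200))
def test_adding_perfect_genuine_never_raises_eer(seed):
    rng = np.random.default_rng(seed)
    n = 50
    probs = rng.random((n, 3))
    y = rng.integers(0, 3, n)
    base = eer(probs, y)
    perfect = np.zeros((1, 3))
    perfect[0, 0] = 1.0
    aug = eer(np.vstack([probs, perfect]), np.append(y, 0))
    assert aug <= base + 1e-12


def test_eer_rejects_degenerate_input():
    with pytest.raises(ValueError):
        eer(np.array([[1.0]]), np.array([0]))
    with pytest.raises(ValueError):
        eer(np.empty((0, 3)), np.empty(0, dtype=int))


def test_far_frr_are_monotone():
    rng = np.random.default_rng(3)
    probs = rng.random((100, 3))
    y = rng.integers(0, 3, 100)
    _, far, frr = far_frr_curve(probs, y)
    assert np.all(np.diff(far) <= 1e-12)
    assert np.all(np.diff(frr) >= -1e-12)


# ---------------------------------------------------------------------------
# protocols (bookkeeping; identification power is covered by the
# acceptance suite with the full-size network)


def _tiny_factory(n_subjects, seed):
    spec = ModelSpec(n_subjects=n_subjects, conv_maps=(4, 4, 4),
                     fuse_maps=4, fc_dim=16, dropout=0.0)
    return build_model(spec, seed=seed), TrainConfig(epochs=1, batch_size=256,
                                                     lr=1e-3, seed=seed)


@pytest.fixture(scope="module")
def score_data():
    rng = np.random.default_rng(0)
    n_subjects, clips = 15, 48
    X = rng.standard_normal((n_subjects * clips, 20, 9, 9)).astype(np.float32)
    y = np.repeat(np.arange(n_subjects), clips)
    return X, y


def test_kfold_fold_sizes_and_determinism(score_data):
    X, y = score_data
    rep_a = kfold_protocol(X, y, _tiny_factory, k=10, seed=3)
    rep_b = kfold_protocol(X, y, _tiny_factory, k=10, seed=3)
    assert len(rep_a.folds) == 10
    assert all(f["n_test"] == 72 for f in rep_a.folds)       # 720 / 10
    assert sum(f["n_test"] for f in rep_a.folds) == len(y)   # folds cover the set
    assert [f["rank1"] for f in rep_a.folds] == [f["rank1"] for f in rep_b.folds]
    assert 0 <= rep_a.rank1_mean <= 1
    # an untrained scorer sits at chance
    assert rep_a.eer_mean == pytest.approx(0.5, abs=0.05)


def test_kfold_rejects_underfilled_subjects():
    X = np.zeros((12, 20, 9, 9), np.float32)
    y = np.array([0] * 6 + [1] * 6)
    with pytest.raises(ValueError):
        kfold_protocol(X, y, _tiny_factory, k=10)


def test_cross_condition_partitions(score_data):
    X, y = score_data
    tags = np.where(np.arange(len(y)) % 3 == 0, "positive", "neutral")
    res = cross_condition(X, y, tags, "positive", "neutral", _tiny_factory, seed=1)
    assert res["n_test"] == (tags == "neutral").sum()
    same = cross_condition(X, y, tags, "positive", "positive", _tiny_factory, seed=1)
    assert same["n_test"] == pytest.approx(0.1 * (tags == "positive").sum(), abs=1)
    with pytest.raises(ValueError):
        cross_condition(X, y, tags, "negative", "neutral", _tiny_factory)


def test_condition_transfer_single_training(score_data):
    X, y = score_data
    tags = np.where(np.arange(len(y)) % 2 == 0, "positive", "negative")
    res = condition_transfer(X, y, tags, "positive", ("positive", "negative"),
                             _tiny_factory, seed=0)
    assert set(res) >= {"positive", "negative", "n_train"}
    with pytest.raises(ValueError):
        condition_transfer(X, y, tags, "positive", ("neutral",), _tiny_factory)


def test_interval_requires_all_sessions(score_data):
    X, y = score_data
    sessions = np.arange(len(y)) % 2  # only sessions 0 and 1
    with pytest.raises(ValueError):
        interval_protocol(X, y, sessions, _tiny_factory)
    rep = interval_protocol(X, y, np.arange(len(y)) % 3, _tiny_factory, seed=0)
    assert {"rank1_nt", "rank1_interval", "eer_nt", "eer_interval"} <= set(rep.entries)
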