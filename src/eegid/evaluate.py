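"""Biometric metrics and evaluation protocols.

Closed-set identification is scored by rank-1 accuracy (top-scoring identity
equals the true one).  Verification performance is summarized by the equal
error rate (EER): softmax outputs are reduced one-vs-all, the probability a
clip assigns to the true identity is a genuine score and the probabilities
assigned to every wrong identity are impostor scores, and the EER is the
operating point where the false-acceptance and false-rejection rates cross
under an exhaustive threshold sweep (linearly interpolated between adjacent
thresholds).

Three protocols mirror the study designs biometric EEG work cares about:
stratified k-fold identification, cross-condition transfer (train on one
emotion, test on another), and session-interval testing (train on early
sessions, test on a later one).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .model import DECNN, TrainConfig, TrainedModel, predict, train

__all__ = [
    "rank1",
    "eer",
    "far_frr_curve",
    "EvalReport",
    "kfold_protocol",
    "cross_condition",
    "cross_emotion_matrix",
    "interval_protocol",
]

# a model factory builds a fresh untrained net + train config for a fold:
#   factory(n_subjects, seed) -> (DECNN, TrainConfig)
ModelFactory = Callable[[int, int], tuple[DECNN, TrainConfig]]


# ---------------------------------------------------------------------------
# metrics


def rank1(probs: np.ndarray, y_true: np.ndarray) -> float:
    """Fraction of clips whose argmax score is the true identity."""
    probs = np.asarray(probs)
    y_true = np.asarray(y_true)
    if probs.ndim != 2 or probs.shape[0] == 0:
        raise ValueError("need a non-empty (n, n_subjects) score matrix")
    if probs.shape[0] != y_true.shape[0]:
        raise ValueError("scores/labels length mismatch")
    return float(np.mean(probs.argmax(axis=1) == y_true))


def _genuine_impostor(probs: np.ndarray, y_true: np.ndarray):
    probs = np.asarray(probs, dtype=np.float64)
    y_true = np.asarray(y_true)
    if probs.ndim != 2 or probs.shape[1] < 2:
        raise ValueError("verification scoring needs >= 2 identities")
    if probs.shape[0] == 0:
        raise ValueError("empty score set")
    n = probs.shape[0]
    genuine = probs[np.arange(n), y_true]
    mask = np.ones_like(probs, dtype=bool)
    mask[np.arange(n), y_true] = False
    impostor = probs[mask]
    return genuine, impostor


def far_frr_curve(probs: np.ndarray, y_true: np.ndarray):
    """FAR/FRR over the exhaustive threshold sweep.

    FAR(t) = fraction of impostor scores >= t,
    FRR(t) = fraction of genuine scores  < t.
    Sentinel thresholds below/above every score bracket the sweep so the
    curves always cross.
    """
    genuine, impostor = _genuine_impostor(probs, y_true)
    scores = np.unique(np.concatenate([genuine, impostor]))
    thresholds = np.concatenate([[scores[0] - 1.0], scores, [scores[-1] + 1e-9]])
    # vectorized counts via sorted positions
    gs = np.sort(genuine)
    im = np.sort(impostor)
    far = 1.0 - np.searchsorted(im, thresholds, side="left") / im.size
    frr = np.searchsorted(gs, thresholds, side="left") / gs.size
    return thresholds, far, frr


def eer(probs: np.ndarray, y_true: np.ndarray) -> float:
    """Equal error rate from the one-vs-all threshold sweep.

    The crossing of the (piecewise-linear) FAR and FRR curves is found and
    linearly interpolated between the adjacent thresholds.
    """
    _, far, frr = far_frr_curve(probs, y_true)
    diff = far - frr  # starts >= 0 (far=1, frr=0), ends <= 0
    i = int(np.flatnonzero(diff <= 0)[0])
    if i == 0 or diff[i] == 0:
        return float(far[i])
    d0, d1 = diff[i - 1], diff[i]
    a = d0 / (d0 - d1)
    return float(far[i - 1] + a * (far[i] - far[i - 1]))


# ---------------------------------------------------------------------------
# reports


@dataclass
class EvalReport:
    """Protocol result: headline metrics plus fold/condition-level detail."""

    protocol: str
    rank1_mean: float = float("nan")
    rank1_sd: float = float("nan")
    eer_mean: float = float("nan")
    eer_sd: float = float("nan")
    folds: list[dict] = field(default_factory=list)
    entries: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=float))


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(fold,)).generate_state(1)[0] % (2**31))


def _fit_and_score(factory: ModelFactory, n_subjects: int, seed: int,
                   X_tr, y_tr, X_te, y_te) -> tuple[dict, TrainedModel]:
    net, cfg = factory(n_subjects, seed)
    trained = train(net, X_tr, y_tr, cfg)
    probs = predict(trained, X_te)
    return {
        "rank1": rank1(probs, y_te),
        "eer": eer(probs, y_te),
        "n_train": int(len(y_tr)),
        "n_test": int(len(y_te)),
    }, trained


# ---------------------------------------------------------------------------
# protocols


def kfold_protocol(X: np.ndarray, y: np.ndarray, factory: ModelFactory,
                   k: int = 10, seed: int = 0,
                   n_subjects: int | None = None) -> EvalReport:
    """Stratified clip-level k-fold identification (one model per fold)."""
    X = np.asarray(X)
    y = np.asarray(y)
    if n_subjects is None:
        n_subjects = int(y.max()) + 1
    counts = np.bincount(y, minlength=n_subjects)
    if np.any(counts < k):
        bad = np.flatnonzero(counts < k)
        raise ValueError(f"subjects {bad.tolist()} have fewer than k={k} clips")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        if np.unique(y[tr]).size < n_subjects:
            raise ValueError(f"fold {fold}: some subject absent from training split")
        res, _ = _fit_and_score(factory, n_subjects, _fold_seed(seed, fold),
                                X[tr], y[tr], X[te], y[te])
        res["fold"] = fold
        folds.append(res)
    r = np.array([f["rank1"] for f in folds])
    e = np.array([f["eer"] for f in folds])
    return EvalReport(
        protocol=f"{k}-fold identification",
        rank1_mean=float(r.mean()), rank1_sd=float(r.std(ddof=1)),
        eer_mean=float(e.mean()), eer_sd=float(e.std(ddof=1)),
        folds=folds,
    )


def cross_condition(X: np.ndarray, y: np.ndarray, tags: np.ndarray,
                    train_tag: str, test_tag: str, factory: ModelFactory,
                    holdout_frac: float = 0.1, seed: int = 0,
                    n_subjects: int | None = None) -> dict:
    """Train on clips carrying ``train_tag``, evaluate on ``test_tag`` clips.

    A stratified ``holdout_frac`` of the training condition is always set
    aside, so train set size is identical whether the test condition equals
    the training one (hold-out evaluation) or differs (transfer evaluation).
    """
    X, y, tags = np.asarray(X), np.asarray(y), np.asarray(tags)
    if n_subjects is None:
        n_subjects = int(y.max()) + 1
    tr_mask = tags == train_tag
    te_mask = tags == test_tag
    if not tr_mask.any():
        raise ValueError(f"no clips with train condition {train_tag!r}")
    if not te_mask.any():
        raise ValueError(f"no clips with test condition {test_tag!r}")
    idx = np.flatnonzero(tr_mask)
    tr_idx, hold_idx = train_test_split(
        idx, test_size=holdout_frac, random_state=seed, stratify=y[idx])
    if train_tag == test_tag:
        te_idx = hold_idx
    else:
        te_idx = np.flatnonzero(te_mask)
    res, _ = _fit_and_score(factory, n_subjects, _fold_seed(seed, 0),
                            X[tr_idx], y[tr_idx], X[te_idx], y[te_idx])
    res.update({"train": str(train_tag), "test": str(test_tag)})
    return res


def condition_transfer(X: np.ndarray, y: np.ndarray, tags: np.ndarray,
                       train_tag: str, test_tags: tuple[str, ...],
                       factory: ModelFactory, holdout_frac: float = 0.1,
                       seed: int = 0, n_subjects: int | None = None) -> dict:
    """One model trained on ``train_tag``, scored on several test conditions.

    Equivalent to repeated :func:`cross_condition` calls with the same
    training condition, but trains only once.  The training condition itself
    is always scored on its held-out split.
    """
    X, y, tags = np.asarray(X), np.asarray(y), np.asarray(tags)
    if n_subjects is None:
        n_subjects = int(y.max()) + 1
    idx = np.flatnonzero(tags == train_tag)
    if idx.size == 0:
        raise ValueError(f"no clips with train condition {train_tag!r}")
    tr_idx, hold_idx = train_test_split(
        idx, test_size=holdout_frac, random_state=seed, stratify=y[idx])
    net, cfg = factory(n_subjects, _fold_seed(seed, 0))
    trained = train(net, X[tr_idx], y[tr_idx], cfg)
    out = {"train": str(train_tag), "n_train": int(len(tr_idx))}
    for tag in test_tags:
        if tag == train_tag:
            te = hold_idx
        else:
            te = np.flatnonzero(tags == tag)
            if te.size == 0:
                raise ValueError(f"no clips with test condition {tag!r}")
        probs = predict(trained, X[te])
        out[str(tag)] = {"rank1": rank1(probs, y[te]), "eer": eer(probs, y[te]),
                         "n_test": int(len(te))}
    return out


def cross_emotion_matrix(X, y, emotions, factory, seed: int = 0,
                         conditions: tuple[str, ...] | None = None) -> EvalReport:
    """All ordered (train emotion, test emotion) pairs, diagonal included."""
    emotions = np.asarray(emotions)
    if conditions is None:
        conditions = tuple(dict.fromkeys(emotions.tolist()))  # stable order
    entries = {}
    for tr_tag in conditions:
        res = condition_transfer(X, y, emotions, tr_tag, conditions, factory, seed=seed)
        for te_tag in conditions:
            entries[f"{tr_tag}->{te_tag}"] = {
                "train": tr_tag, "test": te_tag, **res[te_tag]}
    same = [v["rank1"] for k, v in entries.items() if k.split("->")[0] == k.split("->")[1]]
    cross = [v["rank1"] for k, v in entries.items() if k.split("->")[0] != k.split("->")[1]]
    return EvalReport(
        protocol="cross-emotion transfer",
        rank1_mean=float(np.mean(cross)), rank1_sd=float(np.std(cross, ddof=1)) if len(cross) > 1 else 0.0,
        entries={**entries,
                 "same_rank1_mean": float(np.mean(same)),
                 "cross_rank1_mean": float(np.mean(cross))},
    )


def interval_protocol(X: np.ndarray, y: np.ndarray, sessions: np.ndarray,
                      factory: ModelFactory,
                      train_sessions: tuple[int, ...] = (0, 1),
                      test_session: int = 2,
                      holdout_frac: float = 0.1, seed: int = 0,
                      n_subjects: int | None = None) -> EvalReport:
    """Train on early sessions, test both on held-out clips from those same
    sessions ("NT", no time interval) and on the later session ("interval")."""
    X, y, sessions = np.asarray(X), np.asarray(y), np.asarray(sessions)
    present = set(np.unique(sessions).tolist())
    needed = set(train_sessions) | {test_session}
    if not needed <= present:
        raise ValueError(f"sessions {sorted(needed - present)} missing from dataset")
    if n_subjects is None:
        n_subjects = int(y.max()) + 1
    tr_all = np.flatnonzero(np.isin(sessions, train_sessions))
    te_interval = np.flatnonzero(sessions == test_session)
    tr_idx, nt_idx = train_test_split(
        tr_all, test_size=holdout_frac, random_state=seed, stratify=y[tr_all])
    net, cfg = factory(n_subjects, _fold_seed(seed, 0))
    trained = train(net, X[tr_idx], y[tr_idx], cfg)
    p_nt = predict(trained, X[nt_idx])
    p_iv = predict(trained, X[te_interval])
    entries = {
        "rank1_nt": rank1(p_nt, y[nt_idx]),
        "rank1_interval": rank1(p_iv, y[te_interval]),
        "eer_nt": eer(p_nt, y[nt_idx]),
        "eer_interval": eer(p_iv, y[te_interval]),
        "n_train": int(len(tr_idx)),
        "n_nt": int(len(nt_idx)),
        "n_interval": int(len(te_interval)),
    }
    return EvalReport(
        protocol="session-interval",
        rank1_mean=entries["rank1_interval"],
        eer_mean=entries["eer_interval"],
        entries=entries,
    )
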