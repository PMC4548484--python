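"""Evaluation statistics: accuracy, variance ratios, sensitivity/specificity,
stratified splitting, and the optimal-fractional-order sweep.

The angle sweep evaluates the full FrCC pipeline at every rotation angle on
a grid inside (0, pi), with one train/test split shared across angles, and
reports the accuracy profile together with the best angle.  The variance
ratio R compares how tightly two feature sets cluster about their mean
vectors (R < 1: numerator features more concentrated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateDenominatorError,
    InsufficientDataError,
    UndefinedRateError,
)
from . import hmm as hmm_mod
from . import lda as lda_mod
from .features import FrameParams, FrccConfig, batch_extract
from .types import LABEL_DECEPTIVE, LABEL_NORMAL, Utterance

__all__ = [
    "ConfusionCounts",
    "SweepResult",
    "variance_ratio",
    "sensitivity_specificity",
    "accuracy",
    "split_train_test",
    "angle_sweep",
    "default_alpha_grid",
]


def default_alpha_grid(n: int = 99) -> np.ndarray:
    """Interior grid {0.01*pi, ..., 0.99*pi} (step 0.01*pi by default).

    The endpoints 0 and pi are degenerate fractional orders, so a step of
    0.01*pi over (0, pi) yields 99 usable points.
    """
    return np.pi * np.arange(1, n + 1) / (n + 1)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion table with the deceptive class as positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class SweepResult:
    """Accuracy profile over the fractional-order grid."""

    grid: np.ndarray
    accuracy_per_alpha: np.ndarray
    best_alpha: float
    best_accuracy: float
    sensitivity_per_alpha: np.ndarray | None = None
    specificity_per_alpha: np.ndarray | None = None
    classifier: str = "lda"

    def accuracy_at(self, alpha: float) -> float:
        idx = int(np.argmin(np.abs(self.grid - alpha)))
        if not np.isclose(self.grid[idx], alpha, atol=1e-9):
            raise KeyError(f"alpha {alpha} not on the sweep grid")
        return float(self.accuracy_per_alpha[idx])


def variance_ratio(feat_a: np.ndarray, feat_b: np.ndarray) -> float:
    """Ratio of summed squared deviations about the mean vector.

    R = sum_i ||a_i - a_bar||^2 / sum_j ||b_j - b_bar||^2.  R < 1 means
    ``feat_a`` is more concentrated about its center.
    """
    a = np.atleast_2d(np.asarray(feat_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(feat_b, dtype=np.float64))
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature sets must share the dimension")
    num = float(((a - a.mean(axis=0)) ** 2).sum())
    den = float(((b - b.mean(axis=0)) ** 2).sum())
    if den == 0.0:
        raise DegenerateDenominatorError("denominator features are all identical")
    return num / den


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(FP+TN)); raises naming the rate on empty denominators."""
    if c.tp + c.fn == 0:
        raise UndefinedRateError("sensitivity undefined: no positive samples (TP+FN=0)")
    if c.fp + c.tn == 0:
        raise UndefinedRateError("specificity undefined: no negative samples (FP+TN=0)")
    return c.tp / (c.tp + c.fn), c.tn / (c.fp + c.tn)


def accuracy(c: ConfusionCounts) -> float:
    """(TP+TN) / total."""
    if c.total == 0:
        raise UndefinedRateError("accuracy undefined on an empty table")
    return (c.tp + c.tn) / c.total


def split_train_test(
    utterances: Sequence[Utterance], fraction: float = 0.30, seed: int = 0
) -> tuple[list[Utterance], list[Utterance]]:
    """Per-class stratified utterance-level split, reproducible under seed.

    The train share per class is ``fraction`` rounded half-down, clipped so
    both sides are non-empty.  Splitting whole utterances (rather than
    frames) keeps overlapping frames of one recording out of both sides.
    """
    rng = np.random.default_rng(seed)
    by_label: dict = {}
    for u in utterances:
        by_label.setdefault(u.label, []).append(u)
    train: list[Utterance] = []
    test: list[Utterance] = []
    for label in sorted(by_label, key=str):
        group = by_label[label]
        if len(group) < 2:
            raise InsufficientDataError(
                f"class {label!r} has {len(group)} utterance(s); need >= 2"
            )
        n_train = ceil(fraction * len(group) - 0.5)  # round half down
        n_train = min(max(n_train, 1), len(group) - 1)
        order = rng.permutation(len(group))
        train.extend(group[i] for i in order[:n_train])
        test.extend(group[i] for i in order[n_train:])
    return train, test


def _confusion_from_pairs(true_labels, predicted) -> ConfusionCounts:
    t = np.asarray(true_labels)
    p = np.asarray(predicted)
    return ConfusionCounts(
        tp=int(np.sum((t == LABEL_DECEPTIVE) & (p == LABEL_DECEPTIVE))),
        fp=int(np.sum((t == LABEL_NORMAL) & (p == LABEL_DECEPTIVE))),
        tn=int(np.sum((t == LABEL_NORMAL) & (p == LABEL_NORMAL))),
        fn=int(np.sum((t == LABEL_DECEPTIVE) & (p == LABEL_NORMAL))),
    )


def _evaluate_lda(train_feats, test_feats) -> ConfusionCounts:
    """Frame-level LDA: every frame vector is classified independently."""
    X1 = np.vstack([f.vectors for f in train_feats if f.label == LABEL_NORMAL])
    X2 = np.vstack([f.vectors for f in train_feats if f.label == LABEL_DECEPTIVE])
    model = lda_mod.fit(X1, X2, labels=(LABEL_NORMAL, LABEL_DECEPTIVE))
    truths, preds = [], []
    for f in test_feats:
        pred = lda_mod.decide(lda_mod.project(f.vectors, model), model)
        preds.append(np.asarray(pred))
        truths.append(np.full(f.n_frames, f.label))
    return _confusion_from_pairs(np.concatenate(truths), np.concatenate(preds))


def _evaluate_hmm(train_feats, test_feats, n_states, n_symbols, seed) -> ConfusionCounts:
    """Utterance-level HMM: per-class models, maximum-likelihood decision."""
    pooled = np.vstack([f.vectors for f in train_feats])
    codebook = hmm_mod.vq_fit(pooled, n_symbols, seed=seed)
    models = {}
    for label in (LABEL_NORMAL, LABEL_DECEPTIVE):
        seqs = [hmm_mod.vq_assign(f.vectors, codebook)
                for f in train_feats if f.label == label]
        models[label] = hmm_mod.baum_welch_fit(
            seqs, n_states=n_states, n_symbols=n_symbols, seed=seed, n_restarts=3
        )
    truths, preds = [], []
    for f in test_feats:
        pred = hmm_mod.classify(f, codebook, models[LABEL_NORMAL],
                                models[LABEL_DECEPTIVE],
                                labels=(LABEL_NORMAL, LABEL_DECEPTIVE))
        preds.append(pred)
        truths.append(f.label)
    return _confusion_from_pairs(truths, preds)


def evaluate_at_alpha(
    train_utts: Sequence[Utterance],
    test_utts: Sequence[Utterance],
    alpha: float,
    params: FrameParams,
    config: FrccConfig | None = None,
    classifier: str = "lda",
    n_states: int = hmm_mod.DEFAULT_STATES,
    n_symbols: int = hmm_mod.DEFAULT_SYMBOLS,
    seed: int = 0,
) -> ConfusionCounts:
    """Train and evaluate one classifier at one fractional order."""
    config = config or FrccConfig()
    feats = batch_extract(list(train_utts) + list(test_utts), config, params, [alpha])
    seqs = feats[float(alpha)]
    train_feats, test_feats = seqs[:len(train_utts)], seqs[len(train_utts):]
    if classifier == "lda":
        return _evaluate_lda(train_feats, test_feats)
    if classifier == "hmm":
        return _evaluate_hmm(train_feats, test_feats, n_states, n_symbols, seed)
    raise ValueError(f"unknown classifier {classifier!r}")


def angle_sweep(
    utterances: Sequence[Utterance],
    grid: Sequence[float],
    params: FrameParams,
    config: FrccConfig | None = None,
    classifier: str = "lda",
    fraction: float = 0.30,
    seed: int = 0,
    n_states: int = hmm_mod.DEFAULT_STATES,
    n_symbols: int = hmm_mod.DEFAULT_SYMBOLS,
) -> SweepResult:
    """Accuracy profile of the chosen classifier over the fractional grid.

    One stratified 30/70 utterance split is shared by every angle.
    Duplicate grid entries collapse to a single evaluation.  Ties in best
    accuracy are broken toward the angle closest to pi/2 (the conventional
    transform wins when fractional orders offer no gain).
    """
    grid = np.asarray(list(grid), dtype=np.float64)
    if grid.size == 0:
        raise ValueError("alpha grid must be non-empty")
    if np.any(grid <= 0) or np.any(grid >= np.pi):
        raise ValueError("alpha grid must lie strictly inside (0, pi)")
    unique = np.unique(grid)
    config = config or FrccConfig()
    train_utts, test_utts = split_train_test(utterances, fraction=fraction, seed=seed)
    feats = batch_extract(list(train_utts) + list(test_utts), config, params, unique)
    accs = np.zeros(unique.size)
    sens = np.zeros(unique.size)
    spec = np.zeros(unique.size)
    for i, alpha in enumerate(unique):
        seqs = feats[float(alpha)]
        train_feats, test_feats = seqs[:len(train_utts)], seqs[len(train_utts):]
        if classifier == "lda":
            counts = _evaluate_lda(train_feats, test_feats)
        elif classifier == "hmm":
            counts = _evaluate_hmm(train_feats, test_feats, n_states, n_symbols, seed)
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
        accs[i] = accuracy(counts)
        se, sp = sensitivity_specificity(counts)
        sens[i], spec[i] = se, sp
    best = accs.max()
    tied = np.flatnonzero(np.isclose(accs, best, atol=0, rtol=0))
    best_idx = tied[np.argmin(np.abs(unique[tied] - np.pi / 2))]
    return SweepResult(
        grid=unique,
        accuracy_per_alpha=accs,
        best_alpha=float(unique[best_idx]),
        best_accuracy=float(best),
        sensitivity_per_alpha=sens,
        specificity_per_alpha=spec,
        classifier=classifier,
    )
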