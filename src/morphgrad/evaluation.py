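"""Evaluation protocol: stratified k-fold splitting and AUC.

AUC is preferred over thresholded accuracy because scorer outputs can
carry an arbitrary, fluctuating bias toward 0 or 1; AUC depends only on
the ranking. Per-fold values are always reported individually — with small
test folds the spread across folds is large and the mean alone hides it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .gradients import ScoringFunction
from .synthetic import LabeledMeshSet


@dataclass(frozen=True)
class FoldAssignment:
    """Per-sample fold index in [0, k), stratified by class."""

    fold_index: np.ndarray
    k: int
    rng_seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def stratified_kfold(labels: Sequence[int], k: int, rng_seed: int = 0) -> FoldAssignment:
    """Stratified fold assignment: shuffle within each class, then deal
    round-robin, offsetting each class's starting fold so overall fold
    sizes stay within one of n/k.

    Every class must have at least k members.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(rng_seed)
    fold_index = np.full(len(labels), -1, dtype=int)
    offset = 0
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if len(members) < k:
            raise ValueError(
                f"class {cls} has {len(members)} members, fewer than k={k}")
        rng.shuffle(members)
        fold_index[members] = (np.arange(len(members)) + offset) % k
        offset += len(members)
    return FoldAssignment(fold_index, k, rng_seed)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, i.e. the Mann-Whitney statistic: the
    fraction of (positive, negative) pairs ranked correctly, ties counted
    half. Undefined (error) when only one class is present."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def accuracy_at_threshold(scores: Sequence[float], labels: Sequence[int],
                          threshold: float = 0.5) -> float:
    """Plain accuracy at a fixed threshold (provided for completeness;
    AUC is the default metric)."""
    labels = np.asarray(labels, dtype=int)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return float((pred == labels).mean())


@dataclass
class CrossValResult:
    fold_aucs: list[float]
    fold_sizes: list[int]
    folds: FoldAssignment

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


ScorerFactory = Callable[[LabeledMeshSet], ScoringFunction]


def cross_validated_auc(dataset: LabeledMeshSet, scorer_factory: ScorerFactory,
                        k: int = 5, rng_seed: int = 0) -> CrossValResult:
    """Stratified k-fold cross-validation of a scorer-producing procedure.

    For each fold, ``scorer_factory`` is given the training subset and must
    return a ScoringFunction, which is then evaluated by AUC on the
    held-out fold. Returns all k per-fold AUCs (the mean is a convenience
    property, never the only output).
    """
    folds = stratified_kfold(dataset.labels, k, rng_seed)
    fold_aucs: list[float] = []
    fold_sizes: list[int] = []
    for fold in range(k):
        train = dataset.subset(folds.train_indices(fold))
        test_idx = folds.test_indices(fold)
        test = dataset.subset(test_idx)
        scorer = scorer_factory(train)
        scores = [scorer(m) for m in test.meshes]
        fold_aucs.append(auc(scores, test.labels))
        fold_sizes.append(len(test_idx))
    return CrossValResult(fold_aucs, fold_sizes, folds)


def write_fold_csv(result: CrossValResult, path) -> None:
    """CSV output: fold, n_test, AUC, plus a trailing mean row."""
    lines = ["fold,n_test,auc"]
    for i, (a, n) in enumerate(zip(result.fold_aucs, result.fold_sizes)):
        lines.append(f"{i},{n},{a:.6f}")
    lines.append(f"mean,{sum(result.fold_sizes)},{result.mean_auc:.6f}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
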