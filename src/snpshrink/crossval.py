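"""k-fold cross-validation with a shrinkage grid.

Samples are randomly divided into 10 (by default) near-equal partitions;
each partition in turn is the test set and the rest the training set.  A
trial is one random partition; several trials are run and accuracies
averaged.  Accuracy is the fraction of correctly classified test samples
over all test samples.  The full Delta-accuracy curve is reported;
``best_delta`` is the largest Delta attaining the maximum mean accuracy
(parsimony tie-break), which tunes on the test curve and is therefore
optimistic as a generalization estimate.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .centroid import ShrunkenCentroid
from .io import GenotypeMatrix


def kfold_split(n: int, k: int, labels=None, seed: int = 0,
                stratified: bool = True) -> list[np.ndarray]:
    """Partition range(n) into k folds with sizes differing by at most 1.

    With ``stratified`` (requires ``labels``) each class is spread as
    evenly as possible over the folds.  Deterministic for a given seed.
    """
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} samples")
    rng = np.random.default_rng(seed)
    if stratified and labels is not None:
        labels = np.asarray(labels, dtype=object)
        order = []
        for lab in sorted(set(labels)):
            idx = np.flatnonzero(labels == lab)
            order.extend(rng.permutation(idx))
        order = np.array(order)
    else:
        order = rng.permutation(n)
    # round-robin deal keeps fold sizes within 1 of each other globally
    # and, with the class-blocked order, within 1 per class as well
    return [order[f::k] for f in range(k)]


@dataclasses.dataclass
class CVResult:
    """Cross-validation output over a Delta grid."""

    folds: list[np.ndarray]
    delta_grid: np.ndarray
    accuracy_per_delta: np.ndarray       # mean over trials
    accuracy_per_trial: np.ndarray       # (trials, len(grid))
    best_delta: float
    confusion: np.ndarray                # K x K counts at best_delta
    class_labels: list

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracy_per_delta.max())


def confusion_accuracy(confusion) -> float:
    """Overall accuracy of a K x K confusion count matrix: trace / total."""
    c = np.asarray(confusion)
    if np.any(c < 0):
        raise ValueError("confusion counts must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(c) / total)


def default_delta_grid() -> np.ndarray:
    """Delta from 0 to 3 in steps of 0.1."""
    return np.round(np.arange(0.0, 3.0 + 1e-9, 0.1), 10)


def cross_validate(g: GenotypeMatrix, delta_grid=None, seed: int = 0, *,
                   folds: int = 10, trials: int = 1, stratified: bool = True,
                   model_cls=ShrunkenCentroid, **model_kw) -> CVResult:
    """k-fold cross-validation of the shrunken-centroid classifier.

    For each trial (random re-partition), fold and Delta: fit on the
    training samples, classify the test samples.  Returns per-trial and
    mean accuracies, the best Delta, and the confusion matrix pooled over
    folds and trials at the best Delta.
    """
    if g.labels is None:
        raise ValueError("labels required for cross-validation")
    class_labels = g.classes()
    if len(class_labels) < 2:
        raise ValueError("need at least 2 classes")
    if delta_grid is None:
        delta_grid = default_delta_grid()
    delta_grid = np.asarray(delta_grid, dtype=float)
    K = len(class_labels)
    lab_idx = {lab: i for i, lab in enumerate(class_labels)}

    acc = np.zeros((trials, len(delta_grid)))
    # predictions kept so the confusion matrix at best_delta needs no refit
    preds: list[list[tuple[np.ndarray, np.ndarray]]] = [
        [] for _ in delta_grid]  # per delta: (true_idx, pred_idx) per fold
    first_folds: list[np.ndarray] = []
    for t in range(trials):
        fold_sets = kfold_split(g.n_samples, folds, labels=g.labels,
                                seed=seed + t, stratified=stratified)
        if t == 0:
            first_folds = fold_sets
        counts = np.zeros(len(delta_grid))
        total = 0
        for test_idx in fold_sets:
            train_idx = np.setdiff1d(np.arange(g.n_samples), test_idx)
            train = g.subset_samples(train_idx)
            test = g.subset_samples(test_idx)
            if len(set(train.labels)) < K:
                warnings.warn("a training fold is missing a class; "
                              "that class is dropped for this fold")
            model = model_cls(train, **model_kw)
            true = np.array([lab_idx[l] for l in test.labels])
            for di, delta in enumerate(delta_grid):
                res = model.fit(delta)
                pred = res.predict(test.calls)
                pred_idx = np.array([lab_idx[l] for l in pred])
                counts[di] += int((pred_idx == true).sum())
                preds[di].append((true, pred_idx))
            total += len(test_idx)
        acc[t] = counts / total

    mean_acc = acc.mean(axis=0)
    # largest delta among maximizers: the most parsimonious model
    best_i = int(np.flatnonzero(mean_acc == mean_acc.max())[-1])
    best_delta = float(delta_grid[best_i])
    confusion = np.zeros((K, K), dtype=int)
    for true, pred in preds[best_i]:
        np.add.at(confusion, (true, pred), 1)
    return CVResult(
        folds=first_folds,
        delta_grid=delta_grid,
        accuracy_per_delta=mean_acc,
        accuracy_per_trial=acc,
        best_delta=best_delta,
        confusion=confusion,
        class_labels=class_labels,
    )
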