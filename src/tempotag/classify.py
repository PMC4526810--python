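"""Difference-feature LDA classification with greedy forward channel selection.

Per-trial differences of the per-channel beat amplitudes between the two
paired recordings form one category; sign-inverted copies form the second.
Because the construction is antisymmetric the optimal boundary passes through
the origin, which a pooled-covariance linear discriminant finds naturally.
Channels are chosen greedily by cross-validated accuracy; cross-validation
keeps each difference vector and its mirror image in the same fold so that no
information leaks between training and test partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError
from .stats import TrialPair

__all__ = [
    "DifferenceFeatureSet",
    "LDAModel",
    "CVResult",
    "build_difference_dataset",
    "lda_fit",
    "forward_select",
    "cross_validate",
    "evaluate_on_subject_averages",
]


@dataclass
class DifferenceFeatureSet:
    """Antisymmetric two-category dataset of per-channel amplitude differences.

    Row ``i`` (label +1) and row ``n/2 + i`` (label -1 and negated features)
    derive from the same underlying trial; ``pair_ids`` records that link so
    that cross-validation can assign both members to the same fold.
    """

    X: np.ndarray
    y: np.ndarray
    channel_labels: tuple[str, ...]
    level: str  # "trial" | "subject_average"
    pair_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.pair_ids = np.asarray(self.pair_ids, dtype=int)
        if self.X.shape[0] != self.y.size or self.X.shape[0] != self.pair_ids.size:
            raise InvalidInputError("X, y and pair_ids must agree in sample count")
        if self.X.shape[1] != len(self.channel_labels):
            raise InvalidInputError("column count must match channel_labels")

    def columns(self, labels: Sequence[str]) -> np.ndarray:
        idx = [self.channel_labels.index(l) for l in labels]
        return self.X[:, idx]


@dataclass
class LDAModel:
    """Pooled-covariance linear discriminant: predict sign(w.x + b)."""

    weights: np.ndarray
    bias: float
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    pooled_covariance: np.ndarray
    selected_channels: tuple[str, ...] = ()

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, 1, -1)


@dataclass
class CVResult:
    """Repeated k-fold cross-validation outcome."""

    mean_accuracy: float
    per_iteration: np.ndarray
    folds: int
    iterations: int
    seed: int
    selected_channels: tuple[str, ...] = ()


def build_difference_dataset(
    pairs: Sequence[TrialPair],
    paradigm: str,
    level: str = "trial",
    channel_labels: Sequence[str] | None = None,
) -> DifferenceFeatureSet:
    """Assemble the two-category difference dataset from analyzed trial pairs.

    Category +1 holds the per-channel differences (B - A: scrambled - original
    or ignored - attended) per trial; category -1 holds their negations.  With
    ``level="subject_average"`` rows are the means over each subject's trials.
    """
    if not pairs:
        raise InvalidInputError("no trial pairs supplied")
    if any(p.paradigm != paradigm for p in pairs):
        raise InvalidInputError("mixed paradigms in one dataset")
    first = pairs[0]
    if first.channel_amplitudes_a is None or first.channel_amplitudes_b is None:
        raise InvalidInputError("pairs lack per-channel beat amplitudes")
    if channel_labels is None:
        channel_labels = tuple(first.channel_amplitudes_a)
    diffs, keys = [], []
    for p in pairs:
        if p.channel_amplitudes_a is None or p.channel_amplitudes_b is None:
            raise InvalidInputError("pairs lack per-channel beat amplitudes")
        missing = [c for c in channel_labels
                   if c not in p.channel_amplitudes_a or c not in p.channel_amplitudes_b]
        if missing:
            raise InvalidInputError(f"missing channels {missing} in pair "
                                    f"(subject {p.subject}, trial {p.trial})")
        diffs.append([p.channel_amplitudes_b[c] - p.channel_amplitudes_a[c]
                      for c in channel_labels])
        keys.append(p.subject)
    D = np.asarray(diffs, dtype=float)
    if level == "subject_average":
        subjects = sorted(set(keys))
        D = np.vstack([D[[k == s for k in keys]].mean(axis=0) for s in subjects])
    elif level != "trial":
        raise InvalidInputError(f"unknown level {level!r}")
    n = D.shape[0]
    X = np.vstack([D, -D])
    y = np.concatenate([np.ones(n, dtype=int), -np.ones(n, dtype=int)])
    pair_ids = np.concatenate([np.arange(n), np.arange(n)])
    return DifferenceFeatureSet(X=X, y=y, channel_labels=tuple(channel_labels),
                                level=level, pair_ids=pair_ids)


def lda_fit(
    X: np.ndarray,
    y: np.ndarray,
    regularization_eps: float = 1e-10,
    channel_labels: Sequence[str] = (),
) -> LDAModel:
    """Fit the pooled-covariance linear discriminant.

    ``w = pooled_cov^-1 (mu_pos - mu_neg)``; the bias places the boundary
    midway between the projected class means (equal priors).  The pooled
    covariance receives a ridge of ``regularization_eps * trace / dim`` on the
    diagonal so that duplicated or constant features remain solvable.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise InvalidInputError("exactly two classes are required")
    pos, neg = X[y == classes.max()], X[y == classes.min()]
    if len(pos) < 2 or len(neg) < 2:
        raise InvalidInputError("need at least two samples per class")
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    # pooled within-class scatter with n - 2 denominator
    cov = (
        (pos - mu_p).T @ (pos - mu_p) + (neg - mu_n).T @ (neg - mu_n)
    ) / (len(pos) + len(neg) - 2)
    dim = X.shape[1]
    ridge = regularization_eps * (np.trace(cov) / dim if np.trace(cov) > 0 else 1.0)
    cov_r = cov + ridge * np.eye(dim)
    try:
        w = np.linalg.solve(cov_r, mu_p - mu_n)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(cov_r, mu_p - mu_n, rcond=None)[0]
    b = float(-0.5 * w @ (mu_p + mu_n))
    return LDAModel(weights=w, bias=b, mean_pos=mu_p, mean_neg=mu_n,
                    pooled_covariance=cov, selected_channels=tuple(channel_labels))


def _paired_folds(
    pair_ids: np.ndarray, y: np.ndarray, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random fold assignment keeping mirrored rows together, stratified by class.

    When every pair id occurs in both classes (the antisymmetric construction)
    pairs are dealt to folds directly, which is automatically stratified.
    Otherwise rows are dealt per class.
    """
    unique = np.unique(pair_ids)
    pairs_are_mirrored = all(
        len(np.unique(y[pair_ids == u])) == 2 for u in unique
    )
    fold_of_row = np.empty(len(y), dtype=int)
    if pairs_are_mirrored:
        order = rng.permutation(unique)
        for rank, u in enumerate(order):
            fold_of_row[pair_ids == u] = rank % folds
    else:
        # iterate classes by first occurrence so the partition is invariant
        # under a simultaneous label flip (y -> -y)
        _, first = np.unique(y, return_index=True)
        for i in np.sort(first):
            rows = np.flatnonzero(y == y[i])
            rows = rng.permutation(rows)
            for rank, r in enumerate(rows):
                fold_of_row[r] = rank % folds
    return [np.flatnonzero(fold_of_row == f) for f in range(folds)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    iterations: int = 100,
    seed: int = 0,
    pair_ids: np.ndarray | None = None,
    regularization_eps: float = 1e-10,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the linear discriminant.

    Each iteration draws a fresh random partition; the iteration accuracy is
    the pooled correct fraction over all held-out folds, and ``mean_accuracy``
    averages the iterations.  Deterministic given ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n = len(y)
    if np.unique(y).size != 2:
        raise InvalidInputError("both classes must be present")
    if pair_ids is None:
        pair_ids = np.arange(n)
    n_units = np.unique(pair_ids).size
    if folds > n_units:
        warnings.warn(f"reducing folds from {folds} to {n_units} (too few samples)")
        folds = n_units
    rng = np.random.default_rng(seed)
    accuracies = np.empty(iterations)
    for it in range(iterations):
        fold_rows = _paired_folds(pair_ids, y, folds, rng)
        correct = 0
        for test_rows in fold_rows:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_rows] = False
            model = lda_fit(X[train_mask], y[train_mask], regularization_eps)
            correct += int(np.sum(model.predict(X[test_rows]) == y[test_rows]))
        accuracies[it] = correct / n
    return CVResult(
        mean_accuracy=float(accuracies.mean()),
        per_iteration=accuracies,
        folds=folds,
        iterations=iterations,
        seed=seed,
    )


def forward_select(
    X: np.ndarray,
    y: np.ndarray,
    max_features: int = 2,
    folds: int = 10,
    iterations: int = 100,
    seed: int = 0,
    pair_ids: np.ndarray | None = None,
    channel_labels: Sequence[str] | None = None,
) -> list[int] | list[str]:
    """Greedy forward selection of the channels most informative for LDA.

    At each step the candidate maximizing mean cross-validated accuracy is
    added (same CV partitions for every candidate; ties broken by channel
    order); selection stops when no candidate strictly improves the accuracy
    or ``max_features`` is reached.  Returns channel indices, or labels when
    ``channel_labels`` is given.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if max_features < 1:
        raise InvalidInputError("max_features must be >= 1")
    n_channels = X.shape[1]
    if n_channels < 1:
        raise InvalidInputError("need at least one candidate channel")
    selected: list[int] = []
    best_acc = -np.inf
    while len(selected) < min(max_features, n_channels):
        scores = np.full(n_channels, -np.inf)
        for j in range(n_channels):
            if j in selected:
                continue
            cols = selected + [j]
            scores[j] = cross_validate(
                X[:, cols], y, folds=folds, iterations=iterations,
                seed=seed, pair_ids=pair_ids,
            ).mean_accuracy
        j_best = int(np.argmax(scores))  # argmax takes the first = channel order
        if scores[j_best] <= best_acc:
            break
        selected.append(j_best)
        best_acc = scores[j_best]
    if channel_labels is not None:
        return [channel_labels[j] for j in selected]
    return selected


def evaluate_on_subject_averages(
    model: LDAModel, subject_set: DifferenceFeatureSet
) -> float:
    """Accuracy of a trial-trained model on the subject-average rows.

    The model is reused with its trial-fitted weights; only the channels it
    was trained on are consumed from the subject-level feature set.
    """
    if not model.selected_channels:
        raise InvalidInputError("model does not record its selected channels")
    missing = [c for c in model.selected_channels if c not in subject_set.channel_labels]
    if missing:
        raise InvalidInputError(f"subject-level set lacks channels {missing}")
    Xs = subject_set.columns(model.selected_channels)
    return float(np.mean(model.predict(Xs) == subject_set.y))
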