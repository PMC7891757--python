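"""Expertise classification from transition-probability matrices.

Each recording's m x m transition-probability matrix is flattened row-major
into an m^2-long feature vector (100 features for the ten-AOI cockpit
model).  Features are reduced by PCA and classified with a cosine-distance
K-nearest-neighbours vote under stratified k-fold cross-validation.  The
achieved accuracy is judged against an exact binomial chance level: the
smallest accuracy that random guessing would reach with probability below
alpha.

To avoid train/test leakage the PCA is fitted inside each training fold by
default (the requested component count is capped at the training fold's
rank); fitting once on the full table is available for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .errors import InputError, StratificationError
from .markov import TransitionMatrix


@dataclass(frozen=True)
class FeatureTable:
    """Per-recording feature rows with group labels."""

    X: np.ndarray
    y: np.ndarray
    m: int | None = None  # AOI count when rows are flattened matrices

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise InputError("X must be 2-D with one label per row")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n_rows(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.X.shape[1])


@dataclass(frozen=True)
class ClassificationReport:
    """Cross-validated KNN outcome."""

    fold_accuracies: tuple[float, ...]
    overall_accuracy: float
    confusion: np.ndarray  # rows = true class, cols = predicted, class order = `classes`
    classes: tuple
    chance_level: float
    n_components: int
    metadata: dict = field(default_factory=dict)


def build_feature_table(
    matrices: Sequence[TransitionMatrix], labels: Sequence
) -> FeatureTable:
    """Flatten transition-probability matrices row-major into feature rows.

    Feature order is fixed: feature ``(i - 1) * m + (j - 1)`` is the
    probability of the transition AOI i -> AOI j.
    """
    if len(matrices) == 0:
        raise InputError("no matrices given")
    if len(labels) != len(matrices):
        raise InputError("labels must align with matrices")
    ms = {tm.m for tm in matrices}
    if len(ms) > 1:
        raise InputError(f"matrices have mixed AOI counts: {sorted(ms)}")
    m = ms.pop()
    X = np.stack([tm.probabilities.ravel(order="C") for tm in matrices])
    return FeatureTable(X=X, y=np.asarray(labels), m=m)


def _feasible_components(n_rows: int, n_features: int) -> int:
    return min(n_rows - 1, n_features)


def reduce_dimensions(table: FeatureTable, n_components: int = 35) -> FeatureTable:
    """Project the mean-centered table onto its top principal components.

    A request exceeding the feasible rank ``min(rows - 1, features)`` is
    capped with a warning (a 32-recording table cannot support more than 31
    components).
    """
    if n_components < 1:
        raise InputError("n_components must be >= 1")
    cap = _feasible_components(table.n_rows, table.n_features)
    if n_components > cap:
        warnings.warn(
            f"n_components={n_components} exceeds feasible maximum {cap}; capping",
            stacklevel=2,
        )
        n_components = cap
    pca = PCA(n_components=n_components, svd_solver="full")
    Xr = pca.fit_transform(table.X)
    return FeatureTable(X=Xr, y=table.y, m=None)


def _knn_vote(
    dist: np.ndarray, labels: np.ndarray, classes: Sequence
) -> object:
    """Majority vote with deterministic tie-breaks: a tied vote goes to the
    class with the smallest summed neighbour distance, then to the lowest
    class in sort order."""
    best = None
    for cls in classes:  # classes are sorted, so last tie-break is implicit
        mask = labels == cls
        votes = int(mask.sum())
        if votes == 0:
            continue
        key = (-votes, float(dist[mask].sum()))
        if best is None or key < best[0]:
            best = (key, cls)
    return best[1]


def crossvalidated_knn(
    table: FeatureTable,
    k_folds: int = 5,
    neighbors: int = 10,
    metric: str = "cosine",
    n_components: int | None = 35,
    seed: int = 0,
    reduce_within_fold: bool = True,
) -> ClassificationReport:
    """Stratified k-fold cross-validation of a cosine-distance KNN.

    Cosine distance is ``1 - cosine similarity``.  With ``n_components``
    set, PCA runs inside each training fold (leakage-free) unless
    ``reduce_within_fold=False``, in which case it is fitted once on the
    full table before splitting.  Fold assignment is reproducible from
    *seed*.
    """
    classes = tuple(sorted(np.unique(table.y).tolist()))
    if len(classes) < 2:
        raise InputError("need at least 2 classes")
    counts = {c: int((table.y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < k_folds]
    if small:
        raise StratificationError(
            f"classes {small} have fewer members than k_folds={k_folds}"
        )

    X_full = table.X
    used_components = table.n_features
    if n_components is not None and not reduce_within_fold:
        reduced = reduce_dimensions(table, n_components)
        X_full = reduced.X
        used_components = reduced.n_features

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    y = table.y
    predictions = np.empty(table.n_rows, dtype=y.dtype)
    fold_acc = []
    for train_idx, test_idx in skf.split(X_full, y):
        X_train, X_test = X_full[train_idx], X_full[test_idx]
        if n_components is not None and reduce_within_fold:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fold_cap = min(
                    n_components, _feasible_components(*X_train.shape)
                )
                pca = PCA(n_components=fold_cap, svd_solver="full")
                X_train = pca.fit_transform(X_train)
                X_test = pca.transform(X_test)
            used_components = min(used_components, fold_cap)
        k = min(neighbors, X_train.shape[0])
        nn = NearestNeighbors(n_neighbors=k, metric=metric)
        nn.fit(X_train)
        dist, idx = nn.kneighbors(X_test)
        for row, (d_row, i_row) in enumerate(zip(dist, idx)):
            predictions[test_idx[row]] = _knn_vote(
                d_row, y[train_idx][i_row], classes
            )
        fold_acc.append(float((predictions[test_idx] == y[test_idx]).mean()))

    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    cls_index = {c: i for i, c in enumerate(classes)}
    for true, pred in zip(y, predictions):
        confusion[cls_index[true], cls_index[pred]] += 1
    overall = float(np.trace(confusion) / confusion.sum())
    return ClassificationReport(
        fold_accuracies=tuple(fold_acc),
        overall_accuracy=overall,
        confusion=confusion,
        classes=classes,
        chance_level=binomial_chance_level(table.n_rows, len(classes)),
        n_components=used_components,
        metadata={
            "seed": seed,
            "neighbors": neighbors,
            "metric": metric,
            "k_folds": k_folds,
            "pca_within_fold": bool(reduce_within_fold and n_components),
        },
    )


def binomial_chance_level(
    n: int, n_classes: int = 2, alpha: float = 0.05
) -> float:
    """Smallest accuracy k/n that random guessing beats with probability < alpha.

    Uses the exact upper tail of Binomial(n, 1/n_classes) computed with
    integer arithmetic (no normal approximation).  For n = 32 and two
    classes at alpha = 0.05 this is 22/32 = 68.75%.
    """
    if n < 1 or n_classes < 2:
        raise InputError("need n >= 1 and n_classes >= 2")
    if not (0 < alpha < 1):
        raise InputError("alpha must be in (0, 1)")
    p = Fraction(1, n_classes)
    q = 1 - p
    # tail = P(X >= k), walked upward from k = 0
    tail = Fraction(1)
    for k in range(n + 1):
        if tail < alpha:
            return k / n
        tail -= comb(n, k) * p**k * q ** (n - k)
    return 1.0
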