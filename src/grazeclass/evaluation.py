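"""Cross-validated learner comparison across feature counts.

Four learner types — random forest, RBF support vector machine,
distance-weighted k nearest neighbours and AdaBoost over decision stumps —
are compared under stratified 10-fold cross-validation, optionally swept
over the number of top-ranked features, mirroring the structure of a
behaviour-classification model comparison.

Hyperparameter defaults (the comparison states none, so conventional
baselines are used and surfaced in the config): random forest 500 trees;
SVM radial-basis kernel with C = 1 and training-fold standardisation;
kNN k = 5 distance-weighted; AdaBoost 100 depth-1 trees.

The feature ranking is computed once on the full dataset and reused across
folds by default (matching the sequential rank-then-validate procedure);
``rerank_per_fold=True`` in :func:`sweep_feature_counts` re-ranks inside
each training fold for a strictly leakage-free estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .metrics import ConfusionMatrix
from .relieff import FeatureRanking, ReliefFSelector, rank_features

ALGORITHMS = ("random_forest", "svm", "knn", "adaboost")

DEFAULT_HYPERPARAMETERS = {
    "random_forest": {"n_estimators": 500},
    "svm": {"kernel": "rbf", "C": 1.0},
    "knn": {"n_neighbors": 5, "weights": "distance"},
    "adaboost": {"n_estimators": 100, "max_depth": 1},
}


@dataclass
class CvConfig:
    n_folds: int = 10
    seed: int = 0
    algorithm: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    feature_subset: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; "
                f"choose from {ALGORITHMS}"
            )


@dataclass
class CvResult:
    fold_matrices: list
    pooled_matrix: ConfusionMatrix
    fold_accuracies: list
    mean_accuracy: float
    config: CvConfig

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "fold_accuracies": list(self.fold_accuracies),
            "pooled_matrix": self.pooled_matrix.cells.tolist(),
            "class_names": list(self.pooled_matrix.class_names),
            "config": asdict(self.config),
        }


@dataclass
class SweepResult:
    """Mean CV accuracy per (algorithm, n_features), with per-algorithm argmax."""

    accuracies: dict  # (algorithm, n_features) -> mean accuracy
    argmax: dict      # algorithm -> (n_features, accuracy), smallest n on ties

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, n, acc) for (a, n), acc in sorted(self.accuracies.items())]
        return pd.DataFrame(rows,
                            columns=["algorithm", "n_features", "mean_accuracy"])


def make_learner(algorithm: str, seed: int = 0, hyperparameters: dict | None = None):
    """Instantiate one of the four supported learners with seeded randomness."""
    hp = dict(DEFAULT_HYPERPARAMETERS[algorithm])
    hp.update(hyperparameters or {})
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if algorithm == "svm":
        return make_pipeline(StandardScaler(), SVC(random_state=seed, **hp))
    if algorithm == "knn":
        return KNeighborsClassifier(**hp)
    if algorithm == "adaboost":
        depth = hp.pop("max_depth", 1)
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=depth),
            random_state=seed, **hp)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def stratified_folds(labels, n_folds: int, seed: int) -> list[np.ndarray]:
    """Class-proportion-preserving partition of indices into n_folds test sets."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < n_folds]
    if len(too_small):
        raise ValueError(
            f"class {too_small[0]!r} has fewer than {n_folds} instances"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def _resolve_X(X, feature_subset):
    if isinstance(X, pd.DataFrame):
        if feature_subset:
            missing = set(feature_subset) - set(X.columns)
            if missing:
                raise ValueError(f"unknown features: {sorted(missing)}")
            X = X[list(feature_subset)]
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if feature_subset:
        X = X[:, list(feature_subset)]
    return X


def run_cv(X, y, cfg: CvConfig) -> CvResult:
    """Stratified k-fold cross-validation of one learner.

    Each instance is predicted exactly once, when its fold is held out;
    the pooled confusion matrix accumulates all predictions.
    """
    values = _resolve_X(X, cfg.feature_subset)
    y = np.asarray(y)
    class_names = tuple(np.unique(y))
    folds = stratified_folds(y, cfg.n_folds, cfg.seed)

    fold_matrices, fold_accuracies = [], []
    pooled = np.zeros((len(class_names), len(class_names)))
    all_idx = np.arange(len(y))
    for test_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        learner = make_learner(cfg.algorithm, cfg.seed, cfg.hyperparameters)
        learner.fit(values[train_idx], y[train_idx])
        pred = learner.predict(values[test_idx])
        m = sk_confusion_matrix(y[test_idx], pred, labels=list(class_names))
        fold_matrices.append(ConfusionMatrix(m.astype(float), class_names))
        fold_accuracies.append(float(np.trace(m) / m.sum()))
        pooled += m

    return CvResult(
        fold_matrices=fold_matrices,
        pooled_matrix=ConfusionMatrix(pooled, class_names),
        fold_accuracies=fold_accuracies,
        mean_accuracy=float(np.mean(fold_accuracies)),
        config=cfg,
    )


def sweep_feature_counts(X, y, ranking: FeatureRanking,
                         algorithms=ALGORITHMS, cfg: CvConfig | None = None,
                         n_grid=None, rerank_per_fold: bool = False,
                         relieff_neighbors: int = 100) -> SweepResult:
    """Mean CV accuracy for each algorithm at each feature count.

    ``n_grid`` defaults to every count 1..n_features. With
    ``rerank_per_fold`` the supplied ranking is ignored and ReliefF is
    re-fitted inside each training fold (no ranking leakage).
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("sweep requires a named feature matrix (DataFrame)")
    base = cfg or CvConfig()
    missing = set(X.columns) - set(ranking.names)
    if missing:
        raise ValueError(f"ranking does not cover features: {sorted(missing)}")
    p = X.shape[1]
    grid = list(n_grid) if n_grid is not None else list(range(1, p + 1))

    y = np.asarray(y)
    accuracies: dict = {}
    for algorithm in algorithms:
        for n in grid:
            if rerank_per_fold:
                acc = _cv_rerank(X, y, n, algorithm, base, relieff_neighbors)
            else:
                cfg_n = CvConfig(
                    n_folds=base.n_folds, seed=base.seed, algorithm=algorithm,
                    hyperparameters=base.hyperparameters,
                    feature_subset=ranking.top_n(n),
                )
                acc = run_cv(X, y, cfg_n).mean_accuracy
            accuracies[(algorithm, n)] = acc

    argmax = {}
    for algorithm in algorithms:
        pairs = [(n, accuracies[(algorithm, n)]) for n in grid]
        best = max(pairs, key=lambda t: (t[1], -t[0]))
        argmax[algorithm] = best
    return SweepResult(accuracies=accuracies, argmax=argmax)


def _cv_rerank(X: pd.DataFrame, y, n: int, algorithm: str, base: CvConfig,
               relieff_neighbors: int) -> float:
    """Leakage-free fold loop: rank on the training fold, evaluate held out."""
    folds = stratified_folds(y, base.n_folds, base.seed)
    values = X.to_numpy(dtype=float)
    all_idx = np.arange(len(y))
    accs = []
    for test_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        k = min(relieff_neighbors,
                int(np.bincount(pd.factorize(y[train_idx])[0]).min()) - 1)
        sel = ReliefFSelector(n_neighbors=k).fit(values[train_idx], y[train_idx])
        ranking = rank_features(dict(zip(X.columns, sel.weights_)))
        cols = [X.columns.get_loc(f) for f in ranking.top_n(n)]
        learner = make_learner(algorithm, base.seed, base.hyperparameters)
        learner.fit(values[np.ix_(train_idx, cols)], y[train_idx])
        pred = learner.predict(values[np.ix_(test_idx, cols)])
        accs.append(float(np.mean(pred == y[test_idx])))
    return float(np.mean(accs))
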