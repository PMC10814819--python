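"""PCA-based discriminant analysis, classifier roster and day regression.

Features are standardized (zero mean, unit population SD), condensed to
two principal components (PCA1/PCA2), and a roster of ten classifiers is
evaluated with repeated stratified K-fold cross-validation; out-of-fold
predictions are pooled into per-class correct counts, so the overall
accuracy reproduces "n of m" statements exactly.  Storage day is predicted
with a gradient-boosted regression tree ensemble evaluated out-of-fold.

Classifiers are trained in PCA-2 space by default so the exported decision
surfaces are exact; training in full feature space (with PCA used for
display only) is available via ``use_pca=False``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingRegressor, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, Perceptron
from sklearn.metrics import confusion_matrix, r2_score
from sklearn.model_selection import KFold, RepeatedKFold, RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

#: The ten-classifier roster evaluated on every discrimination problem.
CLASSIFIER_ROSTER = (
    "nearest_centroid",
    "naive_bayes",
    "knn",
    "lda",
    "logistic_regression",
    "perceptron",
    "mlp",
    "random_forest",
    "decision_tree",
    "svm",
)

#: Gradient-boosting hyperparameters, fixed for reproducibility.
GB_PARAMS = dict(n_estimators=500, max_depth=3, learning_rate=0.05, loss="squared_error")


def make_classifier(name: str, seed: int = 0):
    """Instantiate one roster classifier with deterministic settings."""
    factories = {
        "nearest_centroid": lambda: NearestCentroid(),
        "naive_bayes": lambda: GaussianNB(),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "lda": lambda: LinearDiscriminantAnalysis(),
        "logistic_regression": lambda: LogisticRegression(max_iter=2000, random_state=seed),
        "perceptron": lambda: Perceptron(random_state=seed),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=800, random_state=seed
        ),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=200, random_state=seed
        ),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "svm": lambda: SVC(kernel="rbf", random_state=seed),
    }
    if name not in factories:
        raise ValueError(f"unknown classifier {name!r}")
    return factories[name]()


@dataclass
class PCAResult:
    scores: np.ndarray  # n x 2
    loadings: np.ndarray  # 2 x p
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return ((np.asarray(X) - self.mean) / self.scale) @ self.loadings.T


@dataclass
class ClassificationResult:
    classifier: str
    fold_accuracies: np.ndarray
    class_labels: tuple
    correct_per_class: np.ndarray
    total_per_class: np.ndarray
    confusion: np.ndarray

    @property
    def overall_accuracy_pct(self) -> float:
        return 100.0 * self.correct_per_class.sum() / self.total_per_class.sum()

    @classmethod
    def from_counts(cls, correct: Sequence[int], total: Sequence[int], labels=None,
                    classifier: str = "reported") -> "ClassificationResult":
        """Build a result from per-class correct/total counts alone.

        Lets published "n of m correct" statements be turned back into an
        overall accuracy by the same arithmetic used for fresh runs.
        """
        correct = np.asarray(correct, dtype=int)
        total = np.asarray(total, dtype=int)
        if np.any(correct > total):
            raise ValueError("correct counts cannot exceed totals")
        labels = tuple(labels) if labels is not None else tuple(range(len(total)))
        conf = np.diag(correct)
        return cls(classifier, np.array([]), labels, correct, total, conf)


@dataclass
class SubsetSearchResult:
    candidates: pd.DataFrame  # columns: subset, accuracy_pct
    best_subset: tuple[str, ...]
    best_accuracy_pct: float


@dataclass
class RegressionResult:
    predictions: np.ndarray
    actual: np.ndarray
    r2: float
    features: tuple[str, ...]


def standardize(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, StandardScaler]:
    """Center each column to mean 0 and scale to unit population SD."""
    cols = list(columns) if columns is not None else list(table.columns)
    X = table[cols].to_numpy(dtype=float)
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [c for c, s in zip(cols, sds) if s == 0]
        raise ValueError(f"zero-variance columns: {bad}")
    scaler = StandardScaler().fit(X)
    out = table.copy()
    out[cols] = scaler.transform(X)
    return out, scaler


def pca2(X: np.ndarray | pd.DataFrame) -> PCAResult:
    """Top-2 principal components of standardized features.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so repeated runs are bitwise identical.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 samples and >= 2 features")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    pca = PCA(n_components=2, svd_solver="full").fit(Z)
    loadings = pca.components_.copy()
    for k in range(2):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
    scores = Z @ loadings.T
    return PCAResult(scores, loadings, pca.explained_variance_ratio_.copy(), mean, scale)


def _cv_splitter(n_splits: int, n_repeats: int, seed: int, stratified: bool):
    cls = RepeatedStratifiedKFold if stratified else RepeatedKFold
    return cls(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)


def evaluate_classifiers(
    features: np.ndarray | pd.DataFrame,
    labels: Sequence,
    roster: Sequence[str] = CLASSIFIER_ROSTER,
    n_splits: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    use_pca: bool = True,
    stratified: bool = True,
) -> list[ClassificationResult]:
    """Repeated K-fold evaluation of a classifier roster.

    Out-of-fold predictions over all repeats are pooled into per-class
    correct counts; results are sorted by overall accuracy (ties broken
    alphabetically by classifier name).  Standardization and, optionally,
    the PCA-2 projection are fit inside each training fold.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < n_splits]
    if small:
        raise ValueError(
            f"classes {small} have fewer than n_splits={n_splits} members; reduce K"
        )
    cv = _cv_splitter(n_splits, n_repeats, seed, stratified)
    splits = list(cv.split(X, y))
    results = []
    for name in roster:
        fold_acc = []
        correct = np.zeros(len(classes), dtype=int)
        total = np.zeros(len(classes), dtype=int)
        conf = np.zeros((len(classes), len(classes)), dtype=int)
        for train, test in splits:
            scaler = StandardScaler().fit(X[train])
            Xtr, Xte = scaler.transform(X[train]), scaler.transform(X[test])
            if use_pca and X.shape[1] > 2:
                p = PCA(n_components=2, svd_solver="full").fit(Xtr)
                Xtr, Xte = p.transform(Xtr), p.transform(Xte)
            model = make_classifier(name, seed)
            with warnings.catch_warnings():
                # small folds: MLP may stop at max_iter without formal
                # convergence; the pooled accuracy is still well defined
                warnings.simplefilter("ignore")
                model.fit(Xtr, y[train])
            pred = model.predict(Xte)
            fold_acc.append(float(np.mean(pred == y[test])))
            conf += confusion_matrix(y[test], pred, labels=classes)
        correct = np.diag(conf)
        total = conf.sum(axis=1)
        results.append(
            ClassificationResult(
                classifier=name,
                fold_accuracies=np.asarray(fold_acc),
                class_labels=tuple(classes.tolist()),
                correct_per_class=correct,
                total_per_class=total,
                confusion=conf,
            )
        )
    results.sort(key=lambda r: (-r.overall_accuracy_pct, r.classifier))
    return results


def subset_search(
    features: pd.DataFrame,
    labels: Sequence,
    max_subset_size: int = 2,
    classifier: str | None = None,
    n_splits: int = 5,
    n_repeats: int = 3,
    seed: int = 0,
    use_pca: bool = True,
) -> SubsetSearchResult:
    """Exhaustive search over feature subsets up to ``max_subset_size``.

    Each subset is scored by cross-validated accuracy of one classifier
    (the roster winner on the full feature set if not specified).  Feature
    count must stay <= 30 for exhaustive enumeration.
    """
    if max_subset_size < 1:
        raise ValueError("max_subset_size must be >= 1")
    cols = list(features.columns)
    if len(cols) > 30:
        raise ValueError("exhaustive search limited to <= 30 features")
    if classifier is None:
        classifier = evaluate_classifiers(
            features, labels, n_splits=n_splits, n_repeats=n_repeats, seed=seed,
            use_pca=use_pca,
        )[0].classifier
    rows = []
    for k in range(1, max_subset_size + 1):
        for subset in itertools.combinations(cols, k):
            res = evaluate_classifiers(
                features[list(subset)], labels, roster=[classifier],
                n_splits=n_splits, n_repeats=n_repeats, seed=seed, use_pca=use_pca,
            )[0]
            rows.append({"subset": subset, "accuracy_pct": res.overall_accuracy_pct})
    cand = pd.DataFrame(rows).sort_values(
        ["accuracy_pct", "subset"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return SubsetSearchResult(
        candidates=cand,
        best_subset=tuple(cand.loc[0, "subset"]),
        best_accuracy_pct=float(cand.loc[0, "accuracy_pct"]),
    )


def decision_surface(
    model, scores: np.ndarray, grid_step: float = 0.05, padding: float = 0.10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted-label grid over the PCA-score plane for plotting.

    Returns (xx, yy, labels) where xx/yy are 1-D grid axes spanning the
    score bounds padded by ``padding`` on each side.
    """
    scores = np.asarray(scores, dtype=float)
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    span = hi - lo
    lo, hi = lo - padding * span, hi + padding * span
    xx = np.arange(lo[0], hi[0] + grid_step, grid_step)
    yy = np.arange(lo[1], hi[1] + grid_step, grid_step)
    gx, gy = np.meshgrid(xx, yy)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    labels = model.predict(grid).reshape(gy.shape)
    return xx, yy, labels


def gb_day_regression(
    features: np.ndarray | pd.DataFrame,
    days: Sequence[float],
    n_splits: int = 5,
    seed: int = 0,
) -> RegressionResult:
    """Gradient-boosted regression of storage day, scored out-of-fold.

    Predictions from each held-out fold are pooled and R^2 computed on the
    pooled vector (R^2 = 1 - SS_res / SS_tot).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(days, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 distinct day labels")
    names = (
        tuple(features.columns) if isinstance(features, pd.DataFrame)
        else tuple(f"f{i}" for i in range(X.shape[1]))
    )
    cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for train, test in cv.split(X):
        model = GradientBoostingRegressor(random_state=seed, **GB_PARAMS)
        model.fit(X[train], y[train])
        pred[test] = model.predict(X[test])
    return RegressionResult(pred, y, float(r2_score(y, pred)), names)
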