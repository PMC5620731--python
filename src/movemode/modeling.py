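"""Dimension reduction, classification, and efficiency-based model selection.

Two reducers — principal component analysis (feature extraction) and
recursive feature elimination (feature selection, ranked by a random
forest) — are crossed with two classifiers, k-nearest neighbors (k
tuned by leave-one-out cross-validation over 1..100) and random forests
(500 trees, sqrt(p) candidate features per split, Gini splitting).

Each fitted model at reduced dimension i carries an accuracy alpha and
a variance-retained fraction gamma: for PCA, the summed variance
fractions of the kept components; for feature selection, simply i/p,
the kept fraction of the standardized feature set (standardized
features contribute equal variance).  The Model Efficiency Metric

    MEM = alpha * (1 - gamma)

rewards models that are accurate while discarding most of the raw
feature variance.  The optimal model of a family maximizes MEM subject
to alpha >= 0.9 * alpha_max, where alpha_max is the family's best
accuracy; the constraint keeps the selection from trading too much
accuracy for compactness.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import NearestNeighbors

from .core import MODES

logger = logging.getLogger(__name__)

RF_TREES = 500


# ---------------------------------------------------------------------------
# Standardization


@dataclass
class Standardization:
    """Per-feature centering and unit-variance scaling, fit on training rows."""

    mean: pd.Series
    std: pd.Series

    @classmethod
    def fit(cls, table: pd.DataFrame) -> "Standardization":
        if len(table) < 2:
            raise ValueError("need at least 2 training rows to standardize")
        mean = table.mean()
        std = table.std(ddof=1)
        zero = std[std == 0.0]
        if len(zero):
            raise ValueError(f"zero-variance feature column(s): {list(zero.index)}")
        return cls(mean=mean, std=std)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table[self.mean.index] - self.mean) / self.std

    def invert(self, table: pd.DataFrame) -> pd.DataFrame:
        return table * self.std + self.mean


def standardize_fit(table: pd.DataFrame) -> Standardization:
    return Standardization.fit(table)


def standardize_apply(standardization: Standardization, table: pd.DataFrame) -> pd.DataFrame:
    return standardization.apply(table)


# ---------------------------------------------------------------------------
# Reducers


@dataclass
class PCAReducer:
    """Fitted principal components of the standardized training table."""

    pca: PCA
    feature_names: list[str]

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    @property
    def n_components(self) -> int:
        return self.pca.n_components_


def pca_fit(standardized: pd.DataFrame) -> PCAReducer:
    """Fit all principal components, ordered by decreasing variance."""
    pca = PCA(svd_solver="full")
    pca.fit(standardized.to_numpy(dtype=float))
    return PCAReducer(pca=pca, feature_names=list(standardized.columns))


def pca_project(reducer: PCAReducer, table: pd.DataFrame, i: int) -> np.ndarray:
    """Coordinates of rows on the top ``i`` principal components."""
    if not 1 <= i <= reducer.n_components:
        raise ValueError(f"i={i} outside 1..{reducer.n_components}")
    X = table[reducer.feature_names].to_numpy(dtype=float)
    return reducer.pca.transform(X)[:, :i]


@dataclass
class RFEReducer:
    """A full backward-elimination feature ranking plus its CV curve.

    ``ranking`` lists all feature names from best to worst; ``cv_curve``
    maps subset size j to the 10-fold cross-validated accuracy of a
    random forest trained on the top-j features.
    """

    ranking: list[str]
    cv_curve: dict = field(default_factory=dict)
    n_features: int = 0

    def top(self, i: int) -> list[str]:
        if not 1 <= i <= self.n_features:
            raise ValueError(f"i={i} outside 1..{self.n_features}")
        return self.ranking[:i]


def rfe_rank(
    standardized: pd.DataFrame,
    labels,
    folds: int = 10,
    seed: int = 0,
    n_trees: int = RF_TREES,
    cv_sizes=None,
    cv_trees: int | None = None,
) -> RFEReducer:
    """Rank all features by recursive elimination with a random forest.

    Elimination removes one feature at a time (the least important by
    mean decrease in Gini), yielding a total order.  For each subset
    size in ``cv_sizes`` (default: every size 1..p) the accuracy of a
    random forest on the top-j features is estimated by stratified
    ``folds``-fold cross-validation.  ``cv_trees`` lets the curve use a
    lighter forest than the ranking (defaults to ``n_trees``).
    """
    y = np.asarray(labels)
    p = standardized.shape[1]
    strata = pd.Series(y).value_counts().min()
    if folds > strata:
        raise ValueError(f"folds={folds} exceeds smallest class stratum ({strata})")
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", criterion="gini", random_state=seed
    )
    rfe = RFE(rf, n_features_to_select=1, step=1)
    rfe.fit(standardized.to_numpy(dtype=float), y)
    # ranking_ gives 1 for the last-surviving feature, larger = dropped earlier
    order = np.argsort(rfe.ranking_, kind="stable")
    ranking = [standardized.columns[i] for i in order]

    sizes = range(1, p + 1) if cv_sizes is None else cv_sizes
    cv_trees = n_trees if cv_trees is None else cv_trees
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    curve = {}
    X = standardized
    for j in sizes:
        rf_j = RandomForestClassifier(
            n_estimators=cv_trees, max_features="sqrt", criterion="gini", random_state=seed
        )
        scores = cross_val_score(rf_j, X[ranking[:j]].to_numpy(dtype=float), y, cv=skf)
        curve[int(j)] = float(scores.mean())
    return RFEReducer(ranking=ranking, cv_curve=curve, n_features=p)


def variance_retained(reducer, i: int) -> float:
    """Fraction of original feature variance a reduced model keeps.

    PCA keeps the summed variance fractions of its top ``i`` components;
    feature selection keeps ``i / p`` — on standardized features every
    feature carries an equal share of the total variance.
    """
    if isinstance(reducer, PCAReducer):
        if not 1 <= i <= reducer.n_components:
            raise ValueError(f"i={i} outside 1..{reducer.n_components}")
        return float(reducer.variance_fractions[:i].sum())
    if isinstance(reducer, RFEReducer):
        if not 1 <= i <= reducer.n_features:
            raise ValueError(f"i={i} outside 1..{reducer.n_features}")
        return i / reducer.n_features
    raise TypeError(f"unknown reducer type {type(reducer)!r}")


# ---------------------------------------------------------------------------
# Classifiers


def gini_impurity(proportions) -> float:
    """Gini impurity sum(p_i * (1 - p_i)) of class proportions."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()}")
    return float(np.sum(p * (1.0 - p)))


@dataclass
class KNNFit:
    """k-nearest-neighbor classifier with LOOCV-selected k.

    Keeps the training design so predictions are exact majority votes
    over Euclidean neighbors; vote ties are broken by seeded randomness.
    """

    X: np.ndarray
    y: np.ndarray
    k: int
    loocv_curve: dict
    seed: int = 0

    @property
    def loocv_accuracy(self) -> float:
        return self.loocv_curve[self.k]

    def predict(self, X_new) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        nn = NearestNeighbors(n_neighbors=self.k).fit(self.X)
        _, idx = nn.kneighbors(X_new)
        return _majority_vote(self.y[idx], self.seed)


def _majority_vote(label_matrix: np.ndarray, seed: int) -> np.ndarray:
    """Row-wise plurality vote with random tie-breaking."""
    rng = np.random.default_rng(seed)
    out = np.empty(label_matrix.shape[0], dtype=object)
    for r in range(label_matrix.shape[0]):
        labels, counts = np.unique(label_matrix[r], return_counts=True)
        winners = labels[counts == counts.max()]
        out[r] = winners[0] if len(winners) == 1 else rng.choice(winners)
    return out


def fit_knn(X, y, k_range=range(1, 101), seed: int = 0) -> KNNFit:
    """Tune k by leave-one-out cross-validation and return the fit.

    Every candidate k is scored by LOOCV on the training design (each
    point classified by its k nearest *other* points); the k with the
    best LOOCV accuracy wins, smaller k on ties.  The sweep is truncated
    with a warning when the training set is too small for the largest k.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n == 0:
        raise ValueError("empty training set")
    k_range = [k for k in k_range]
    kmax = max(k_range)
    if kmax > n - 1:
        warnings.warn(f"training set of {n} supports k up to {n - 1}; truncating sweep")
        k_range = [k for k in k_range if k <= n - 1]
        kmax = max(k_range)
    nn = NearestNeighbors(n_neighbors=kmax + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = idx[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    curve = {}
    labels_all = y[neigh]
    for k in k_range:
        votes = labels_all[:, :k]
        correct = 0
        for r in range(n):
            labels, counts = np.unique(votes[r], return_counts=True)
            winners = labels[counts == counts.max()]
            pred = winners[0] if len(winners) == 1 else rng.choice(winners)
            correct += pred == y[r]
        curve[k] = correct / n
    best_k = max(k_range, key=lambda k: (curve[k], -k))
    return KNNFit(X=X, y=y, k=best_k, loocv_curve=curve, seed=seed)


def fit_rf(X, y, trees: int = RF_TREES, seed: int = 0) -> RandomForestClassifier:
    """A 500-tree random forest with sqrt(p) features per Gini split."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        warnings.warn("single-class training data; forest is degenerate")
    rf = RandomForestClassifier(
        n_estimators=trees,
        max_features="sqrt",
        criterion="gini",
        bootstrap=True,
        random_state=seed,
    )
    rf.fit(np.asarray(X, dtype=float), y)
    return rf


# ---------------------------------------------------------------------------
# Evaluation and selection


def evaluate(predictions, truth):
    """Confusion proportions, accuracy and per-mode recall of predictions.

    Returns ``(confusion, accuracy, recall)``: a row-stochastic
    DataFrame indexed by true mode, the overall fraction correct, and a
    Series of per-mode recalls (the confusion diagonal).
    """
    predictions = np.asarray(predictions, dtype=object)
    truth = np.asarray(truth, dtype=object)
    counts = pd.crosstab(
        pd.Categorical(truth, categories=MODES),
        pd.Categorical(predictions, categories=MODES),
        dropna=False,
    )
    counts.index = pd.Index(MODES, name="true")
    counts.columns = pd.Index(MODES, name="predicted")
    totals = counts.sum(axis=1)
    confusion = counts.div(totals.replace(0, np.nan), axis=0).dropna(how="all")
    accuracy = float((predictions == truth).mean())
    recall = pd.Series({m: confusion.loc[m, m] for m in confusion.index}, name="recall")
    return confusion, accuracy, recall


def compute_mem(alpha: float, gamma: float) -> float:
    """Model Efficiency Metric: accuracy weighted by variance removed."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    return alpha * (1.0 - gamma)


@dataclass
class ModelFit:
    """One (reducer, dimension, classifier) combination with its scores."""

    reducer_type: str  # "pca" | "rfe" | "none"
    dim: int
    classifier: str  # "knn" | "rf"
    alpha: float
    gamma: float
    test_accuracy: float | None = None
    test_confusion: pd.DataFrame | None = None
    test_recall: pd.Series | None = None
    detail: dict = field(default_factory=dict)

    @property
    def mem(self) -> float:
        return compute_mem(self.alpha, self.gamma)


@dataclass
class SelectionResult:
    """The constrained MEM argmax over a model family."""

    chosen: ModelFit
    alpha_max: float
    feasible: list[bool]
    family: list[ModelFit]


def select_optimal(family: list[ModelFit]) -> SelectionResult:
    """Pick the MEM-maximizing model with alpha >= 0.9 * alpha_max.

    The accuracy-maximizing model is always feasible, so the feasible
    set is never empty.  MEM ties are broken toward the smaller
    dimension, then family order.
    """
    if not family:
        raise ValueError("empty model family")
    alpha_max = max(m.alpha for m in family)
    feasible = [m.alpha >= 0.9 * alpha_max for m in family]
    candidates = [m for m, ok in zip(family, feasible) if ok]
    chosen = max(candidates, key=lambda m: (m.mem, -m.dim))
    return SelectionResult(chosen=chosen, alpha_max=alpha_max, feasible=feasible, family=family)


# ---------------------------------------------------------------------------
# Family builders: one ModelFit per reduced dimension


def fit_pca_family(
    X_train: pd.DataFrame,
    y_train,
    classifier: str,
    dims=None,
    variance_cap: float = 0.95,
    seed: int = 0,
    folds: int = 10,
    rf_trees: int = RF_TREES,
    cv_trees: int | None = None,
    X_test: pd.DataFrame | None = None,
    y_test=None,
) -> tuple[list[ModelFit], PCAReducer, Standardization]:
    """PCA-reduced kNN or RF models over a range of component counts.

    ``dims`` defaults to 1..i95 where i95 is the smallest component
    count retaining ``variance_cap`` of the variance.  alpha is the
    10-fold CV accuracy for RF and the LOOCV accuracy at the tuned k
    for kNN, both computed on the projected training rows.
    """
    std = Standardization.fit(X_train)
    Z = std.apply(X_train)
    reducer = pca_fit(Z)
    if dims is None:
        cum = np.cumsum(reducer.variance_fractions)
        i95 = int(np.searchsorted(cum, variance_cap) + 1)
        dims = range(1, min(i95, reducer.n_components) + 1)
    Z_test = std.apply(X_test) if X_test is not None else None
    fits = []
    for i in dims:
        P = pca_project(reducer, Z, i)
        alpha, model = _fit_classifier(P, y_train, classifier, seed, folds, rf_trees, cv_trees)
        fit = ModelFit(
            reducer_type="pca",
            dim=i,
            classifier=classifier,
            alpha=alpha,
            gamma=variance_retained(reducer, i),
        )
        if Z_test is not None:
            preds = model.predict(pca_project(reducer, Z_test, i))
            fit.test_confusion, fit.test_accuracy, fit.test_recall = evaluate(preds, y_test)
        fits.append(fit)
    return fits, reducer, std


def fit_rfe_family(
    X_train: pd.DataFrame,
    y_train,
    classifier: str,
    dims,
    seed: int = 0,
    folds: int = 10,
    rf_trees: int = RF_TREES,
    cv_trees: int | None = None,
    X_test: pd.DataFrame | None = None,
    y_test=None,
    reducer: RFEReducer | None = None,
) -> tuple[list[ModelFit], RFEReducer, Standardization]:
    """RFE-reduced kNN or RF models over a range of feature counts.

    The one forest-based ranking is shared by both classifier families.
    alpha comes from the reducer's CV curve for RF models and from kNN
    LOOCV for kNN models, on the standardized top-i features.
    """
    std = Standardization.fit(X_train)
    Z = std.apply(X_train)
    dims = list(dims)
    if reducer is None:
        reducer = rfe_rank(
            Z,
            y_train,
            folds=folds,
            seed=seed,
            n_trees=rf_trees,
            cv_sizes=dims if classifier == "rf" else [],
            cv_trees=cv_trees,
        )
    Z_test = std.apply(X_test) if X_test is not None else None
    fits = []
    for i in dims:
        cols = reducer.top(i)
        if classifier == "rf" and i in reducer.cv_curve:
            alpha = reducer.cv_curve[i]
            model = fit_rf(Z[cols].to_numpy(), y_train, trees=rf_trees, seed=seed)
        else:
            alpha, model = _fit_classifier(
                Z[cols].to_numpy(), y_train, classifier, seed, folds, rf_trees, cv_trees
            )
        fit = ModelFit(
            reducer_type="rfe",
            dim=i,
            classifier=classifier,
            alpha=alpha,
            gamma=variance_retained(reducer, i),
        )
        if Z_test is not None:
            preds = model.predict(Z_test[cols].to_numpy())
            fit.test_confusion, fit.test_accuracy, fit.test_recall = evaluate(preds, y_test)
        fits.append(fit)
    return fits, reducer, std


def _fit_classifier(X, y, classifier: str, seed: int, folds: int, rf_trees: int,
                    cv_trees: int | None = None):
    """Fit one classifier and estimate its training accuracy (CV/LOOCV)."""
    if classifier == "knn":
        fit = fit_knn(X, y, seed=seed)
        return fit.loocv_accuracy, fit
    if classifier == "rf":
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        rf = RandomForestClassifier(
            n_estimators=cv_trees or rf_trees, max_features="sqrt", criterion="gini",
            random_state=seed,
        )
        alpha = float(cross_val_score(rf, np.asarray(X, dtype=float), np.asarray(y), cv=skf).mean())
        return alpha, fit_rf(X, y, trees=rf_trees, seed=seed)
    raise ValueError(f"unknown classifier {classifier!r}")


def feature_importance(rf: RandomForestClassifier, feature_names) -> pd.Series:
    """Mean decrease in Gini impurity per feature, descending."""
    return pd.Series(rf.feature_importances_, index=list(feature_names)).sort_values(
        ascending=False
    )
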