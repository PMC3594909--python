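"""Four binary classifiers under one contract.

Every method exposes the same surface: ``fit(X, y)`` on a 0/1-labelled
matrix, a continuous per-sample ``score_samples(X)`` in [0, 1] (probability
of class 1), a hard ``predict(X)``, and a per-variable importance used for
ranking:

========  ==========================================  =====================
method    model                                       importance
========  ==========================================  =====================
rf        bagged unit-vote forest of CART trees       Gini score (mean
          (unpruned, mtry = floor(sqrt(p)), minimum   impurity decrease,
          terminal node size 2, 200 trees)            affinely scaled 1-100)
pls       PLS regression on the 0/1 response          VIP
          (PLS-DA), 2 latent components
lda       linear discriminant with diagonal-loaded    |discriminant
          (shrunk) pooled covariance                  coefficient|
svm       linear soft-margin SVM, C = 1               SVM-RFE elimination
                                                      order
========  ==========================================  =====================

The forest casts one unit vote per tree (the most popular class in the
leaf), and its training-set score is the *out-of-bag* vote fraction: for
each sample, the share of class-1 votes among the trees whose bootstrap
resample excluded it. LDA and SVM decision values are mapped to [0, 1] by a
logistic so that all four methods share the same ROC and thresholding
machinery; PLS predictions are clipped to [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ValidationError
from .preprocess import PreprocessConfig, preprocess_table
from .tables import FeatureTable

__all__ = [
    "METHODS",
    "ClassifierSpec",
    "RankList",
    "VoteForestClassifier",
    "PLSDAClassifier",
    "RegularizedLDAClassifier",
    "LinearSVMClassifier",
    "fit_classifier",
    "score_samples",
    "predict_class",
    "rank_variables",
    "compute_vip",
    "svm_rfe",
    "scale_gini",
    "mtry",
]

METHODS = ("rf", "pls", "lda", "svm")


def mtry(p: int) -> int:
    """Variables tried per split node: floor of the square root of p."""
    return max(1, int(math.floor(math.sqrt(p))))


@dataclass(frozen=True)
class ClassifierSpec:
    """Declarative configuration for one of the four methods.

    ``rf_n_trees``/``rf_min_node`` follow the stated forest configuration
    (200 trees, terminal nodes of at least 2 samples); ``pls_n_components``,
    ``svm_c`` and ``lda_shrinkage`` are exposed because the corresponding
    choices are not pinned down by the method descriptions.
    """

    method: str
    rf_n_trees: int = 200
    rf_min_node: int = 2
    pls_n_components: int = 2
    svm_c: float = 1.0
    lda_shrinkage: float | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.rf_n_trees < 1:
            raise ValidationError(f"rf_n_trees must be >= 1, got {self.rf_n_trees}")
        if self.rf_min_node < 1:
            raise ValidationError(f"rf_min_node must be >= 1, got {self.rf_min_node}")
        if self.pls_n_components < 1:
            raise ValidationError(
                f"pls_n_components must be >= 1, got {self.pls_n_components}"
            )
        if self.svm_c <= 0:
            raise ValidationError(f"svm_c must be > 0, got {self.svm_c}")

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return replace(self, seed=seed)

    def build(self) -> BaseEstimator:
        """Instantiate the configured estimator (unfitted)."""
        if self.method == "rf":
            return VoteForestClassifier(
                n_trees=self.rf_n_trees,
                min_node=self.rf_min_node,
                random_state=self.seed,
            )
        if self.method == "pls":
            return PLSDAClassifier(n_components=self.pls_n_components)
        if self.method == "lda":
            return RegularizedLDAClassifier(shrinkage=self.lda_shrinkage)
        return LinearSVMClassifier(c=self.svm_c)


@dataclass(frozen=True)
class RankList:
    """Variables ordered most- to least-important, with their raw scores.

    ``scores`` are the method's own importance values (scaled Gini, VIP,
    |LDA coefficient|, or SVM-RFE reverse elimination position) aligned with
    ``variable_ids`` and non-increasing. Ties in the raw importance are
    broken lexicographically on the variable id so rankings are reproducible
    across platforms.
    """

    method: str
    variable_ids: tuple[str, ...]
    scores: np.ndarray
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if len(self.variable_ids) != len(self.scores):
            raise ValidationError("variable_ids and scores lengths differ")
        if len(set(self.variable_ids)) != len(self.variable_ids):
            raise ValidationError("rank list repeats a variable id")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValidationError("rank-list scores must be non-increasing")

    def rank_of(self, variable_ids) -> np.ndarray:
        """1-based rank positions for the requested variable ids."""
        pos = {v: i + 1 for i, v in enumerate(self.variable_ids)}
        missing = [str(v) for v in variable_ids if v not in pos]
        if missing:
            raise ValidationError(f"variables not in rank list: {missing}")
        return np.asarray([pos[v] for v in variable_ids], dtype=int)

    def top(self, k: int) -> tuple[str, ...]:
        return self.variable_ids[:k]


def _order_by_importance(variable_ids, raw: np.ndarray) -> np.ndarray:
    """Indices sorting by descending importance, ties by ascending id."""
    return np.asarray(
        sorted(range(len(raw)), key=lambda j: (-raw[j], str(variable_ids[j]))), dtype=int
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _check_fit_inputs(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D")
    if len(y) != X.shape[0]:
        raise ValidationError(f"y has {len(y)} entries for {X.shape[0]} samples")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains missing or non-finite values")
    if X.shape[0] < 3:
        raise ValidationError(f"need at least 3 samples, got {X.shape[0]}")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError(f"need exactly two classes, got {classes.tolist()}")
    return X, y, classes


class VoteForestClassifier(ClassifierMixin, BaseEstimator):
    """Bagged forest of unpruned CART trees with unit-vote aggregation.

    Each tree is grown on a bootstrap resample (sampling with replacement,
    same size as the training set), considering ``floor(sqrt(p))`` randomly
    chosen candidate variables at every node and keeping terminal nodes of
    at least ``min_node`` samples. A sample's score on new data is the
    fraction of trees voting class 1; on the training data the out-of-bag
    variant restricts the vote to trees that never saw the sample.

    Attributes (after fit)
    ----------------------
    trees_ : list of fitted DecisionTreeClassifier
    oob_scores_ : ndarray — per-training-sample OOB class-1 vote fraction
    oob_counts_ : ndarray — number of trees for which each sample was OOB
    oob_error_ : float — OOB misclassification rate (NaN if a sample was
        never OOB)
    feature_importances_ : ndarray — mean decrease in Gini impurity, averaged
        over trees (each tree's importances sum to 1)
    """

    def __init__(self, n_trees: int = 200, min_node: int = 2, random_state: int | None = None):
        self.n_trees = n_trees
        self.min_node = min_node
        self.random_state = random_state

    def fit(self, X, y):
        X, y, classes = _check_fit_inputs(X, y)
        self.classes_ = classes
        n, p = X.shape
        self.n_features_in_ = p
        self.mtry_ = mtry(p)
        rng = np.random.default_rng(self.random_state)
        y1 = y == classes[1]
        vote1 = np.zeros(n)
        oob_vote1 = np.zeros(n)
        oob_counts = np.zeros(n, dtype=int)
        trees = []
        importances = np.zeros(p)
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            tree = DecisionTreeClassifier(
                criterion="gini",
                max_features=self.mtry_,
                min_samples_leaf=self.min_node,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            pred1 = tree.predict(X) == classes[1]
            vote1 += pred1
            inbag = np.bincount(idx, minlength=n) > 0
            oob = ~inbag
            oob_vote1[oob] += pred1[oob]
            oob_counts[oob] += 1
            importances += tree.feature_importances_
            trees.append(tree)
        self.trees_ = trees
        self.feature_importances_ = importances / self.n_trees
        self.train_scores_ = vote1 / self.n_trees
        self.oob_counts_ = oob_counts
        with np.errstate(invalid="ignore"):
            self.oob_scores_ = np.where(oob_counts > 0, oob_vote1 / np.maximum(oob_counts, 1), np.nan)
        if np.all(oob_counts > 0):
            self.oob_error_ = float(np.mean((self.oob_scores_ > 0.5) != y1))
        else:
            self.oob_error_ = float("nan")
        self._train_X = X.copy()
        return self

    def _check_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"model was trained on {self.n_features_in_} variables, got {X.shape[1]}"
            )
        return X

    def score_samples(self, X) -> np.ndarray:
        """Class-1 vote fraction over all trees."""
        X = self._check_X(X)
        votes = np.zeros(X.shape[0])
        for tree in self.trees_:
            votes += tree.predict(X) == self.classes_[1]
        return votes / self.n_trees

    def oob_score_samples(self) -> np.ndarray:
        """OOB class-1 vote fraction for the training samples."""
        never = np.flatnonzero(self.oob_counts_ == 0)
        if never.size:
            raise ValidationError(
                f"sample position(s) {never.tolist()} were in-bag for every tree; "
                "their OOB score is undefined — increase n_trees"
            )
        return self.oob_scores_

    def predict(self, X):
        scores = self.score_samples(X)
        return np.where(scores > 0.5, self.classes_[1], self.classes_[0])


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS regression on the 0/1 class response (PLS-DA).

    Internal autoscaling is disabled; pretreatment is the preprocessing
    stage's responsibility. Scores are the predicted response clipped to
    [0, 1].
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X, y, classes = _check_fit_inputs(X, y)
        self.classes_ = classes
        n, p = X.shape
        self.n_features_in_ = p
        # requested components are capped at what the data can support
        self.n_components_ = min(self.n_components, n - 1, p)
        if np.all(X.std(axis=0) == 0):
            # information-free input (e.g. a single row-normalised variable):
            # fall back to the base-rate response
            warnings.warn("all variables constant; PLS reduces to the base rate",
                          stacklevel=2)
            self.pls_ = None
            self._base_rate = float(np.mean(y == classes[1]))
            return self
        self.pls_ = PLSRegression(n_components=self.n_components_, scale=False)
        with warnings.catch_warnings():
            # y residuals become constant once separation is achieved
            warnings.simplefilter("ignore", UserWarning)
            self.pls_.fit(X, (y == classes[1]).astype(float))
        return self

    def score_samples(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.pls_ is None:
            return np.full(X.shape[0], np.clip(self._base_rate, 0.0, 1.0))
        return np.clip(self.pls_.predict(X).ravel(), 0.0, 1.0)

    def predict(self, X):
        return np.where(self.score_samples(X) > 0.5, self.classes_[1], self.classes_[0])

    @property
    def vip_(self) -> np.ndarray:
        return compute_vip(self)


class RegularizedLDAClassifier(ClassifierMixin, BaseEstimator):
    """Linear discriminant with diagonal loading of the pooled covariance.

    Plain LDA is singular whenever p exceeds n (187 variables against at
    most 132 samples in the emulated design), so the covariance is shrunk
    toward a scaled identity; ``shrinkage="auto"`` uses the Ledoit-Wolf
    estimate. The signed distance to the discriminant boundary is mapped to
    [0, 1] by a logistic.
    """

    def __init__(self, shrinkage: float | str | None = "auto"):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X, y, classes = _check_fit_inputs(X, y)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self.lda_ = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=self.shrinkage)
        self.lda_.fit(X, y)
        return self

    def score_samples(self, X) -> np.ndarray:
        return expit(self.lda_.decision_function(np.asarray(X, dtype=float)))

    def predict(self, X):
        return np.where(self.score_samples(X) > 0.5, self.classes_[1], self.classes_[0])

    @property
    def coef_(self) -> np.ndarray:
        return self.lda_.coef_


class LinearSVMClassifier(ClassifierMixin, BaseEstimator):
    """Soft-margin SVM with a linear kernel (weight vector required by RFE)."""

    def __init__(self, c: float = 1.0):
        self.c = c

    def fit(self, X, y):
        X, y, classes = _check_fit_inputs(X, y)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self.svc_ = SVC(kernel="linear", C=self.c)
        self.svc_.fit(X, y)
        return self

    def score_samples(self, X) -> np.ndarray:
        return expit(self.svc_.decision_function(np.asarray(X, dtype=float)))

    def predict(self, X):
        return np.where(self.score_samples(X) > 0.5, self.classes_[1], self.classes_[0])

    @property
    def coef_(self) -> np.ndarray:
        return self.svc_.coef_


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over the estimators)
# ---------------------------------------------------------------------------


def fit_classifier(spec: ClassifierSpec, table: FeatureTable):
    """Fit the configured method on a (pretreated) feature table."""
    model = spec.build()
    model.fit(table.values, table.labels)
    return model


def score_samples(model, table: FeatureTable, oob: bool = False) -> np.ndarray:
    """Continuous class-1 scores in [0, 1] for the table's samples.

    ``oob=True`` is valid only for the vote forest scored on its own
    training table and returns the out-of-bag vote fractions.
    """
    if oob:
        if not isinstance(model, VoteForestClassifier):
            raise ValidationError("out-of-bag scores exist only for the rf method")
        if not np.array_equal(np.asarray(table.values, dtype=float), model._train_X):
            raise ValidationError("oob=True requires the model's own training table")
        return model.oob_score_samples()
    return model.score_samples(table.values)


def predict_class(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff score strictly exceeds the threshold (ties go to class 0)."""
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must lie in (0, 1), got {threshold}")
    return (np.asarray(scores, dtype=float) > threshold).astype(int)


def compute_vip(model) -> np.ndarray:
    """Variable importance in projection for a fitted PLS-DA model.

    For variable j over components a with weight vectors w_a, scores t_a and
    response loadings q_a,

        VIP_j = sqrt( p * sum_a SS_a (w_aj / ||w_a||)^2 / sum_a SS_a ),

    where SS_a = q_a^2 t_a' t_a is the response sum of squares explained by
    component a. By construction the VIP^2 values average to 1 across
    variables.
    """
    pls = getattr(model, "pls_", model)
    if not isinstance(pls, PLSRegression):
        raise ValidationError("compute_vip requires a fitted, non-degenerate PLS model")
    W = pls.x_weights_  # (p, A)
    T = pls.x_scores_  # (n, A)
    q = pls.y_loadings_.ravel()  # (A,)
    ss = (q**2) * np.sum(T**2, axis=0)
    wnorm2 = np.sum(W**2, axis=0)
    p = W.shape[0]
    return np.sqrt(p * ((W**2 / wnorm2) @ ss) / ss.sum())


def svm_rfe(table: FeatureTable, spec: ClassifierSpec | None = None) -> RankList:
    """Recursive feature elimination with a linear SVM.

    Repeatedly fits the SVM on the surviving variables and removes the one
    with the smallest squared weight, exactly one per iteration (ties: the
    lexicographically larger id is removed, so smaller ids survive longer).
    Rank 1 is the last survivor; a variable's raw score is its reverse
    elimination position.
    """
    spec = spec or ClassifierSpec("svm")
    if spec.method != "svm":
        raise ValidationError(f"svm_rfe requires method 'svm', got {spec.method!r}")
    y = table.labels
    ids = [str(v) for v in table.variable_ids]
    remaining = list(range(len(ids)))
    eliminated: list[int] = []
    while len(remaining) > 1:
        model = SVC(kernel="linear", C=spec.svm_c)
        model.fit(table.values[:, remaining], y)
        w2 = (model.coef_.ravel()) ** 2
        drop_local = max(
            np.flatnonzero(w2 == w2.min()), key=lambda j: ids[remaining[j]]
        )
        eliminated.append(remaining.pop(int(drop_local)))
    order = remaining + eliminated[::-1]  # most- to least-important
    p = len(ids)
    return RankList(
        method="svm",
        variable_ids=tuple(ids[j] for j in order),
        scores=np.arange(p, 0, -1, dtype=float),
    )


def scale_gini(raw_importances) -> np.ndarray:
    """Affine map of raw Gini importances onto [1, 100].

    The most important variable always maps to 100. An all-equal input is
    degenerate and maps everything to 100 with a warning.
    """
    raw = np.asarray(raw_importances, dtype=float)
    if raw.size == 0:
        raise ValidationError("scale_gini needs at least one importance value")
    lo, hi = raw.min(), raw.max()
    if lo == hi:
        warnings.warn("all importances equal; Gini scores degenerate to 100", stacklevel=2)
        return np.full(raw.shape, 100.0)
    return 1.0 + 99.0 * (raw - lo) / (hi - lo)


def rank_variables(
    spec: ClassifierSpec,
    table: FeatureTable,
    preprocess: PreprocessConfig | None = None,
) -> RankList:
    """Rank all variables with the method's own importance measure.

    When ``preprocess`` is given, the full pretreatment chain is fitted on
    the table before ranking (there is no held-out partition here).
    """
    if preprocess is not None:
        table = preprocess_table(table, preprocess)
    if spec.method == "svm":
        return svm_rfe(table, spec)
    model = fit_classifier(spec, table)
    if spec.method == "rf":
        raw = scale_gini(model.feature_importances_)
    elif spec.method == "pls":
        raw = model.vip_
    else:
        raw = np.abs(model.coef_.ravel())
    order = _order_by_importance(table.variable_ids, raw)
    return RankList(
        method=spec.method,
        variable_ids=tuple(str(table.variable_ids[j]) for j in order),
        scores=raw[order],
    )
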