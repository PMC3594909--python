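"""Classifier evaluation: cross-validation, R²/Q², ROC, variable elimination.

All evaluation here is leakage-free: the pretreatment chain (normalisation,
centring, scaling) is refitted inside every training partition and applied
with those statistics to the held-out samples.

R²/Q² and the permutation diagnostic
------------------------------------
With actual labels y_i in {0, 1} and continuous fitted scores s_i,

    R² = 1 - sum_i (y_i - s_i)² / sum_i (y_i - mean(y))²,

where the s_i come from the model trained on all samples; Q² is the same
quantity with leave-one-out predictions. For the vote forest, the
training-set score is by definition the out-of-bag vote fraction — each
sample is scored only by trees that never saw it — so the forest's R² is
already cross-validated, and its Q² defaults to the same OOB predictions
(the standard forest approximation to leave-one-out; exact n-refit LOO is
available with ``rf_q2="refit"``).

The permutation diagnostic refits the model on randomly permuted labels,
places each permutation at x = |Pearson correlation of permuted with actual
labels| and the actual model at x = 1, and draws the regression line of each
statistic through the actual point and the centroid of the permuted cloud.
The model is judged valid when (1) every permuted R² and Q² lies below the
actual values and (2) the Q² line's intercept at x = 0 is negative.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .classifiers import ClassifierSpec, VoteForestClassifier, rank_variables
from .errors import ValidationError
from .preprocess import PreprocessConfig, make_preprocessor
from .tables import FeatureTable

__all__ = [
    "CVResult",
    "ConfusionMatrix",
    "ROCCurve",
    "PermutationDiagnostic",
    "EliminationCurve",
    "kfold_cv",
    "holdout_cv",
    "cv_scores",
    "confusion_metrics",
    "roc_auc",
    "r_squared",
    "r2_q2",
    "permutation_diagnostic",
    "variable_elimination",
    "min_variables_for_error",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVResult:
    """Per-split error rates of one classifier under one CV scheme."""

    scheme: str
    errors: np.ndarray  # one entry per fold (k-fold) or per repeat (holdout)
    sizes: np.ndarray  # held-out sample count behind each entry

    def __post_init__(self) -> None:
        object.__setattr__(self, "errors", np.asarray(self.errors, dtype=float))
        object.__setattr__(self, "sizes", np.asarray(self.sizes, dtype=int))
        if np.any((self.errors < 0) | (self.errors > 1)):
            raise ValidationError("error rates must lie in [0, 1]")

    @property
    def n_repeats(self) -> int:
        return len(self.errors)

    @property
    def mean_error(self) -> float:
        """Misclassified fraction pooled over the held-out samples."""
        return float(np.average(self.errors, weights=self.sizes))

    @property
    def sd_error(self) -> float:
        return float(np.std(self.errors, ddof=1)) if len(self.errors) > 1 else 0.0

    def boxplot_stats(self) -> dict[str, float]:
        """Quartiles and 1.5-IQR whiskers of the per-split errors."""
        q1, med, q3 = np.percentile(self.errors, [25, 50, 75])
        iqr = q3 - q1
        lo = self.errors[self.errors >= q1 - 1.5 * iqr].min()
        hi = self.errors[self.errors <= q3 + 1.5 * iqr].max()
        return {
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "whisker_low": float(lo),
            "whisker_high": float(hi),
        }


@dataclass(frozen=True)
class ConfusionMatrix:
    true_positive: int
    false_negative: int
    true_negative: int
    false_positive: int

    def __post_init__(self) -> None:
        if min(self.true_positive, self.false_negative, self.true_negative, self.false_positive) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.true_positive + self.false_negative + self.true_negative + self.false_positive


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-sweep ROC: ordered (1 - specificity, sensitivity) points."""

    points: np.ndarray  # (m, 2) array of (fpr, tpr)
    auc: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))


@dataclass(frozen=True)
class PermutationDiagnostic:
    """Actual vs label-permuted R²/Q² with the two validity verdicts."""

    n: int
    r2_actual: float
    q2_actual: float
    perm_correlations: np.ndarray  # |corr(permuted y, actual y)| per permutation
    perm_r2: np.ndarray
    perm_q2: np.ndarray
    r2_intercept: float = field(init=False)
    q2_intercept: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("perm_correlations", "perm_r2", "perm_q2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(
            self,
            "r2_intercept",
            line_intercept(self.r2_actual, self.perm_correlations.mean(), self.perm_r2.mean()),
        )
        object.__setattr__(
            self,
            "q2_intercept",
            line_intercept(self.q2_actual, self.perm_correlations.mean(), self.perm_q2.mean()),
        )

    @property
    def criterion1(self) -> bool:
        """All permuted R² and Q² values below the actual ones."""
        return bool(
            np.all(self.perm_r2 < self.r2_actual) and np.all(self.perm_q2 < self.q2_actual)
        )

    @property
    def criterion2(self) -> bool:
        """Negative vertical intercept of the Q² regression line."""
        return bool(self.q2_intercept < 0)

    @property
    def valid(self) -> bool:
        return self.criterion1 and self.criterion2


@dataclass(frozen=True)
class EliminationCurve:
    """Error rate versus number of retained variables, from p down to 1."""

    steps: tuple[tuple[int, float], ...]  # (variable_count, error_rate)
    elimination_order: tuple[str, ...]  # ids in removal order; last = survivor

    @property
    def counts(self) -> np.ndarray:
        return np.asarray([c for c, _ in self.steps], dtype=int)

    @property
    def errors(self) -> np.ndarray:
        return np.asarray([e for _, e in self.steps], dtype=float)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _sub_seed(master: int, *parts) -> int:
    """Deterministic child seed below 2**31 for a named substream.

    Uses a content hash rather than Python's salted ``hash`` so that seeds
    are stable across processes and platforms.
    """
    digest = hashlib.sha256(
        ("/".join([str(int(master))] + [str(p) for p in parts])).encode()
    ).digest()
    return int.from_bytes(digest[:4], "little") % 2**31


def _fit_predict_split(
    spec: ClassifierSpec,
    table: FeatureTable,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    preprocess: PreprocessConfig | None,
):
    """Fit preprocessing + classifier on the training rows, score the rest."""
    prep = make_preprocessor(preprocess or PreprocessConfig())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # constant columns in small folds
        X_train = prep.fit_transform(table.values[train_idx])
        X_test = prep.transform(table.values[test_idx])
    model = spec.build()
    model.fit(X_train, y[train_idx])
    return model.score_samples(X_test)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def kfold_cv(
    spec: ClassifierSpec,
    table: FeatureTable,
    k: int,
    seed: int = 0,
    preprocess: PreprocessConfig | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation; error pooled over folds.

    Folds are of near-equal size, preprocessing is refitted inside every
    training fold, and the fold assignment is deterministic for a fixed
    seed.
    """
    y = table.labels
    n = table.n_samples
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValidationError(f"k={k} exceeds the sample count {n}")
    counts = np.bincount(y)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        # folds outnumber the smaller class: stratification is impossible,
        # fall back to plain shuffled folds of near-equal size
        warnings.warn(
            f"class counts {counts.tolist()} below k={k}; folds are not stratified",
            stacklevel=2,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    errors, sizes = [], []
    for train_idx, test_idx in splitter.split(table.values, y):
        scores = _fit_predict_split(spec, table, y, train_idx, test_idx, preprocess)
        errors.append(float(np.mean((scores > 0.5) != (y[test_idx] == 1))))
        sizes.append(len(test_idx))
    return CVResult(scheme=f"kfold:{k}", errors=np.asarray(errors), sizes=np.asarray(sizes))


def _holdout_quotas(y: np.ndarray, fraction: float) -> tuple[int, int]:
    """Held-out counts (class 0, class 1): total rounded half up, positive-class
    quota rounded half up, class 0 taking the remainder."""
    n = len(y)
    n1 = int((y == 1).sum())
    total = _round_half_up(fraction * n)
    quota1 = min(_round_half_up(fraction * n1), total)
    return total - quota1, quota1


def holdout_cv(
    spec: ClassifierSpec,
    table: FeatureTable,
    holdout_fraction: float,
    n_repeats: int = 100,
    seed: int = 0,
    preprocess: PreprocessConfig | None = None,
) -> CVResult:
    """Repeated stratified random train/holdout splits at a fixed fraction."""
    if not 0 < holdout_fraction < 1:
        raise ValidationError(f"holdout_fraction must lie in (0, 1), got {holdout_fraction}")
    if n_repeats < 1:
        raise ValidationError(f"n_repeats must be >= 1, got {n_repeats}")
    y = table.labels
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    h0, h1 = _holdout_quotas(y, holdout_fraction)
    if h0 < 1 or h1 < 1:
        raise ValidationError(
            f"holdout_fraction={holdout_fraction} leaves an empty held-out class "
            f"(quotas {h0}/{h1}); increase the fraction"
        )
    if h0 >= len(idx0) or h1 >= len(idx1):
        raise ValidationError(
            f"holdout_fraction={holdout_fraction} empties a training class"
        )
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_repeats):
        hold = np.concatenate(
            [rng.permutation(idx0)[:h0], rng.permutation(idx1)[:h1]]
        )
        train = np.setdiff1d(np.arange(len(y)), hold)
        scores = _fit_predict_split(spec, table, y, train, hold, preprocess)
        errors.append(float(np.mean((scores > 0.5) != (y[hold] == 1))))
    return CVResult(
        scheme=f"holdout:{holdout_fraction:g}",
        errors=np.asarray(errors),
        sizes=np.full(n_repeats, h0 + h1),
    )


def cv_scores(
    spec: ClassifierSpec,
    table: FeatureTable,
    k: int = 7,
    seed: int = 0,
    preprocess: PreprocessConfig | None = None,
) -> np.ndarray:
    """Pooled held-out scores from one stratified k-fold pass (for ROC)."""
    y = table.labels
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    out = np.empty(table.n_samples)
    for train_idx, test_idx in splitter.split(table.values, y):
        out[test_idx] = _fit_predict_split(spec, table, y, train_idx, test_idx, preprocess)
    return out


# ---------------------------------------------------------------------------
# confusion / ROC
# ---------------------------------------------------------------------------


def confusion_metrics(truth, predicted) -> tuple[ConfusionMatrix, float, float]:
    """Confusion counts plus sensitivity TP/(TP+FN) and specificity TN/(TN+FP)."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValidationError(
            f"truth has {truth.shape[0]} entries, predicted has {predicted.shape[0]}"
        )
    if not (set(np.unique(truth)) <= {0, 1} and set(np.unique(predicted)) <= {0, 1}):
        raise ValidationError("labels must be binary 0/1")
    tp = int(np.sum((truth == 1) & (predicted == 1)))
    fn = int(np.sum((truth == 1) & (predicted == 0)))
    tn = int(np.sum((truth == 0) & (predicted == 0)))
    fp = int(np.sum((truth == 0) & (predicted == 1)))
    cm = ConfusionMatrix(tp, fn, tn, fp)

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    return cm, _ratio(tp, tp + fn, "sensitivity"), _ratio(tn, tn + fp, "specificity")


def roc_auc(scores, truth) -> ROCCurve:
    """ROC curve from a threshold sweep with trapezoidal AUC.

    The AUC equals the probability that a random positive outscores a random
    negative, ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        raise ValidationError("ROC needs both classes present in truth")
    fpr, tpr, _ = _sk_roc_curve(truth, scores, drop_intermediate=False)
    return ROCCurve(points=np.column_stack([fpr, tpr]), auc=float(_trapezoid_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# R² / Q² and the permutation diagnostic
# ---------------------------------------------------------------------------


def r_squared(actual, fitted) -> float:
    """1 - SS_residual / SS_total around the mean of the actual labels."""
    actual = np.asarray(actual, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    sst = float(np.sum((actual - actual.mean()) ** 2))
    if sst == 0:
        raise ValidationError("constant labels: R² undefined")
    return 1.0 - float(np.sum((actual - fitted) ** 2)) / sst


def _fitted_scores(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    model = spec.build()
    model.fit(X, y)
    if isinstance(model, VoteForestClassifier):
        return model.oob_score_samples()
    return model.score_samples(X)


def _loo_scores(
    spec: ClassifierSpec,
    table: FeatureTable,
    y: np.ndarray,
    preprocess: PreprocessConfig | None,
) -> np.ndarray:
    n = table.n_samples
    preds = np.empty(n)
    everyone = np.arange(n)
    for i in range(n):
        train = np.delete(everyone, i)
        preds[i] = _fit_predict_split(spec, table, y, train, np.asarray([i]), preprocess)[0]
    return preds


def r2_q2(
    spec: ClassifierSpec,
    table: FeatureTable,
    preprocess: PreprocessConfig | None = None,
    rf_q2: str = "oob",
    _labels: np.ndarray | None = None,
) -> tuple[float, float]:
    """R² from the full-data fit and Q² from leave-one-out predictions.

    ``rf_q2`` selects the forest's leave-one-out strategy: ``"oob"`` (each
    sample predicted by the trees whose bootstrap excluded it; coincides
    with the forest's R², which is OOB-based by definition) or ``"refit"``
    (n exact refits, preprocessing refitted per fold).
    """
    if rf_q2 not in ("oob", "refit"):
        raise ValidationError(f"rf_q2 must be 'oob' or 'refit', got {rf_q2!r}")
    y = table.labels if _labels is None else np.asarray(_labels)
    if table.n_samples < 3:
        raise ValidationError("R²/Q² needs at least 3 samples")
    if len(np.unique(y)) < 2:
        raise ValidationError("constant labels: R²/Q² undefined")
    prep = make_preprocessor(preprocess or PreprocessConfig())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        X = prep.fit_transform(table.values)
    fitted = _fitted_scores(spec, X, y)
    r2 = r_squared(y, fitted)
    if spec.method == "rf" and rf_q2 == "oob":
        q2 = r2  # OOB votes are the forest's leave-one-out surrogate
    else:
        q2 = r_squared(y, _loo_scores(spec, table, y, preprocess))
    return r2, q2


def line_intercept(actual_value: float, perm_x_mean: float, perm_value_mean: float) -> float:
    """Vertical intercept of the line joining the actual point at x = 1 to
    the permuted-cloud centroid."""
    if perm_x_mean == 1.0:
        warnings.warn("permuted correlations all equal 1; intercept undefined", stacklevel=2)
        return float("nan")
    slope = (actual_value - perm_value_mean) / (1.0 - perm_x_mean)
    return actual_value - slope


def permutation_diagnostic(
    spec: ClassifierSpec,
    table: FeatureTable,
    n_perm: int = 100,
    seed: int = 0,
    preprocess: PreprocessConfig | None = None,
    rf_q2: str = "oob",
) -> PermutationDiagnostic:
    """Label-permutation overfitting diagnostic (R²/Q² against label scrambles)."""
    if n_perm < 2:
        raise ValidationError(f"n_perm must be >= 2, got {n_perm}")
    y = table.labels
    r2_actual, q2_actual = r2_q2(spec, table, preprocess, rf_q2)
    rng = np.random.default_rng(seed)
    corrs, perm_r2, perm_q2 = [], [], []
    y_centered = y - y.mean()
    denom = float(np.sum(y_centered**2))
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        corr = abs(float(np.sum((y_perm - y_perm.mean()) * y_centered)) / denom)
        r2_p, q2_p = r2_q2(spec, table, preprocess, rf_q2, _labels=y_perm)
        corrs.append(corr)
        perm_r2.append(r2_p)
        perm_q2.append(q2_p)
    return PermutationDiagnostic(
        n=table.n_samples,
        r2_actual=r2_actual,
        q2_actual=q2_actual,
        perm_correlations=np.asarray(corrs),
        perm_r2=np.asarray(perm_r2),
        perm_q2=np.asarray(perm_q2),
    )


# ---------------------------------------------------------------------------
# recursive variable elimination
# ---------------------------------------------------------------------------


def variable_elimination(
    spec: ClassifierSpec,
    table: FeatureTable,
    k: int = 7,
    seed: int = 0,
    preprocess: PreprocessConfig | None = None,
) -> EliminationCurve:
    """Drop the least important variable one at a time, from p down to 1.

    At every step the surviving variables are re-ranked with the method's
    own importance measure (fitted on the whole current sub-table, after
    pretreatment) and the k-fold CV error of the current sub-table is
    recorded; the lowest-ranked variable is then removed.
    """
    if table.n_variables < 1:
        raise ValidationError("need at least one variable")
    current = table
    steps: list[tuple[int, float]] = []
    removed: list[str] = []
    step = 0
    while True:
        p_now = current.n_variables
        err = kfold_cv(spec, current, k, seed=_sub_seed(seed, "elim", step), preprocess=preprocess)
        steps.append((p_now, err.mean_error))
        if p_now == 1:
            removed.append(str(current.variable_ids[0]))
            break
        ranking = rank_variables(spec, current, preprocess=preprocess or PreprocessConfig())
        worst = ranking.variable_ids[-1]
        removed.append(worst)
        keep = np.asarray([v != worst for v in current.variable_ids])
        current = current.select_variables(keep)
        step += 1
    return EliminationCurve(steps=tuple(steps), elimination_order=tuple(removed))


def min_variables_for_error(curve: EliminationCurve, max_error: float) -> int | None:
    """Smallest retained-variable count whose error is strictly below the cap.

    Returns ``None`` when no step qualifies.
    """
    qualifying = [count for count, error in curve.steps if error < max_error]
    return min(qualifying) if qualifying else None
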