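"""Cross-validation, ROC/AUC, R²/Q², permutation diagnostic, elimination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaboclass import (
    ClassifierSpec,
    EliminationCurve,
    SimConfig,
    ValidationError,
    confusion_metrics,
    generate_dataset,
    holdout_cv,
    kfold_cv,
    line_intercept,
    min_variables_for_error,
    permutation_diagnostic,
    r2_q2,
    r_squared,
    roc_auc,
    variable_elimination,
)
from metaboclass.validation import _holdout_quotas

FAST_SPECS = [ClassifierSpec("pls"), ClassifierSpec("lda"), ClassifierSpec("svm")]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def test_kfold_fold_sizes_partition_the_samples():
    table = generate_dataset(SimConfig(5, 5, 4, 0, 0.0, 2, 0.0, 2, seed=1))
    res = kfold_cv(ClassifierSpec("pls", pls_n_components=1), table, 7, seed=0)
    assert sorted(res.sizes.tolist()) == [1, 1, 1, 1, 2, 2, 2]
    assert res.sizes.sum() == 10


@pytest.mark.parametrize(
    "spec",
    FAST_SPECS + [ClassifierSpec("rf", rf_n_trees=100, seed=2)],
    ids=lambda s: s.method,
)
def test_separable_data_has_near_zero_error(spec):
    table = generate_dataset(SimConfig(20, 20, 10, 4, 5.0, 5, 0.2, 3, seed=2))
    assert kfold_cv(spec, table, 7, seed=1).mean_error <= 0.05


@pytest.mark.parametrize("spec", FAST_SPECS[:2], ids=lambda s: s.method)
def test_null_labels_give_chance_error(spec, null_table):
    errors = [kfold_cv(spec, null_table, 7, seed=s).mean_error for s in range(5)]
    assert abs(np.mean(errors) - 0.5) < 0.1


def test_kfold_validates_inputs(null_table):
    with pytest.raises(ValidationError, match="k"):
        kfold_cv(ClassifierSpec("pls"), null_table, 1)
    with pytest.raises(ValidationError, match="exceeds"):
        kfold_cv(ClassifierSpec("pls"), null_table, 101)


def test_holdout_repeat_count_and_reproducibility(null_table):
    spec = ClassifierSpec("pls")
    res = holdout_cv(spec, null_table, 0.33, n_repeats=100, seed=9)
    assert res.n_repeats == 100
    again = holdout_cv(spec, null_table, 0.33, n_repeats=100, seed=9)
    assert np.array_equal(res.errors, again.errors)
    stats = res.boxplot_stats()
    assert stats["q1"] <= stats["median"] <= stats["q3"]


def test_holdout_sizes_round_half_up():
    # 65 vs 67 design at one third held out: 22 + 22 = 44 samples
    y = np.array([0] * 65 + [1] * 67)
    assert _holdout_quotas(y, 0.33) == (22, 22)
    assert _holdout_quotas(y, 0.10) == (6, 7)  # total 13, positive quota 7


def test_smaller_holdout_fraction_is_noisier():
    table = generate_dataset(SimConfig(66, 66, 20, 5, 1.0, 5, 0.3, 5, seed=13))
    spec = ClassifierSpec("pls")
    sds = {
        frac: holdout_cv(spec, table, frac, n_repeats=100, seed=3).sd_error
        for frac in (0.10, 0.33)
    }
    assert sds[0.10] > sds[0.33]


def test_holdout_degenerate_fraction_rejected(null_table):
    with pytest.raises(ValidationError, match="holdout_fraction"):
        holdout_cv(ClassifierSpec("pls"), null_table, 0.002, n_repeats=2)


# ---------------------------------------------------------------------------
# confusion / ROC
# ---------------------------------------------------------------------------


def test_confusion_metric_formulas():
    truth = [1] * 10 + [0] * 10
    pred = [1] * 9 + [0] + [0] * 8 + [1] * 2
    cm, sens, spec_ = confusion_metrics(truth, pred)
    assert (cm.true_positive, cm.false_negative) == (9, 1)
    assert (cm.true_negative, cm.false_positive) == (8, 2)
    assert sens == pytest.approx(0.9)
    assert spec_ == pytest.approx(0.8)
    assert cm.total == 20
    _, s1, s2 = confusion_metrics([0, 1], [0, 1])
    assert s1 == s2 == 1.0


def test_confusion_undefined_ratio_warns():
    with pytest.warns(UserWarning, match="sensitivity"):
        _, sens, _ = confusion_metrics([0, 0], [0, 1])
    assert np.isnan(sens)
    with pytest.raises(ValidationError, match="entries"):
        confusion_metrics([0, 1], [0, 1, 1])


def _concordance(scores, truth):
    """Brute-force pairwise AUC oracle: ties count one half."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def test_roc_auc_worked_example():
    curve = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    assert curve.auc == pytest.approx(0.75, abs=1e-12)
    assert tuple(curve.points[0]) == (0.0, 0.0)
    assert tuple(curve.points[-1]) == (1.0, 1.0)
    assert np.all(np.diff(curve.points, axis=0) >= 0)


def test_roc_auc_degenerate_scores():
    assert roc_auc([1, 1, 1, 1], [0, 1, 0, 1]).auc == pytest.approx(0.5)
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0
    with pytest.raises(ValidationError, match="classes"):
        roc_auc([0.1, 0.2], [1, 1])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 9), st.booleans()), min_size=4, max_size=50
    ).filter(lambda d: len({t for _, t in d}) == 2)
)
def test_trapezoidal_auc_equals_pairwise_concordance(data):
    scores = np.array([s / 10 for s, _ in data])
    truth = np.array([int(t) for _, t in data])
    assert roc_auc(scores, truth).auc == pytest.approx(
        _concordance(scores, truth), abs=1e-10
    )


# ---------------------------------------------------------------------------
# R² / Q²
# ---------------------------------------------------------------------------


def test_r_squared_examples():
    assert r_squared([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
    assert r_squared([0, 0, 1, 1], [0.5] * 4) == 0.0
    assert r_squared([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(0.90, abs=1e-12)
    with pytest.raises(ValidationError, match="constant"):
        r_squared([1, 1, 1], [0.2, 0.3, 0.4])


@pytest.mark.parametrize("method", ["rf", "pls", "lda", "svm"])
def test_r2_at_least_q2(method):
    hold = []
    for rep in range(12):
        table = generate_dataset(SimConfig(20, 20, 10, 3, 1.0, 5, 0.3, 3, seed=900 + rep))
        spec = ClassifierSpec(method, rf_n_trees=100, seed=rep)
        r2, q2 = r2_q2(spec, table)
        hold.append(r2 >= q2)
    assert np.mean(hold) >= 0.95


def test_rf_oob_q2_close_to_refit_loo_q2():
    table = generate_dataset(SimConfig(20, 20, 10, 3, 1.5, 5, 0.3, 3, seed=42))
    spec = ClassifierSpec("rf", rf_n_trees=200, seed=0)
    _, q2_oob = r2_q2(spec, table, rf_q2="oob")
    _, q2_refit = r2_q2(spec, table, rf_q2="refit")
    assert abs(q2_oob - q2_refit) < 0.15


def test_permutation_intercept_two_point_line():
    # actual Q2 = 0.8 at x = 1, permuted centroid (0.1, -0.2)
    assert line_intercept(0.8, 0.1, -0.2) == pytest.approx(-0.3111, abs=1e-3)


def test_permutation_diagnostic_structure(signal_table):
    diag = permutation_diagnostic(ClassifierSpec("pls"), signal_table, n_perm=10, seed=3)
    assert len(diag.perm_r2) == len(diag.perm_q2) == len(diag.perm_correlations) == 10
    assert np.all((diag.perm_correlations >= 0) & (diag.perm_correlations <= 1))
    assert diag.n == signal_table.n_samples
    assert diag.valid == (diag.criterion1 and diag.criterion2)
    with pytest.raises(ValidationError, match="n_perm"):
        permutation_diagnostic(ClassifierSpec("pls"), signal_table, n_perm=1)


def test_signal_forest_diagnostic_valid(signal_table):
    diag = permutation_diagnostic(
        ClassifierSpec("rf", seed=1), signal_table, n_perm=10, seed=5
    )
    assert diag.criterion1 and diag.criterion2
    assert np.all(diag.perm_q2 < 0)


# ---------------------------------------------------------------------------
# variable elimination
# ---------------------------------------------------------------------------


def test_elimination_curve_contract():
    table = generate_dataset(SimConfig(20, 20, 20, 5, 2.5, 5, 0.2, 5, seed=15))
    curve = variable_elimination(ClassifierSpec("pls"), table, k=7, seed=2)
    assert curve.counts.tolist() == list(range(20, 0, -1))
    assert len(curve.elimination_order) == 20
    assert sorted(curve.elimination_order) == sorted(str(v) for v in table.variable_ids)


def test_elimination_first_step_matches_plain_cv():
    from metaboclass.validation import _sub_seed

    table = generate_dataset(SimConfig(15, 15, 5, 2, 2.0, 5, 0.2, 3, seed=16))
    spec = ClassifierSpec("pls")
    curve = variable_elimination(spec, table, k=7, seed=4)
    direct = kfold_cv(spec, table, 7, seed=_sub_seed(4, "elim", 0))
    assert curve.errors[0] == pytest.approx(direct.mean_error)


def test_elimination_single_variable_table():
    table = generate_dataset(SimConfig(10, 10, 1, 1, 2.0, 1, 0.0, 1, seed=17))
    curve = variable_elimination(ClassifierSpec("pls", pls_n_components=1), table, k=5, seed=1)
    assert curve.counts.tolist() == [1]


def test_elimination_retains_informative_variables():
    table = generate_dataset(SimConfig(25, 25, 20, 5, 2.5, 5, 0.2, 5, seed=18))
    curve = variable_elimination(ClassifierSpec("pls"), table, k=7, seed=6)
    order = list(curve.elimination_order)
    truth_ids = {str(v) for v in table.variable_ids[table.truth]}
    removal_step = {v: i for i, v in enumerate(order)}
    informative_steps = [removal_step[v] for v in truth_ids]
    null_steps = [removal_step[v] for v in removal_step if v not in truth_ids]
    assert np.mean(informative_steps) > np.mean(null_steps)
    # informative panel should not be worse than the single last variable
    err_at_k = dict(curve.steps)[5]
    err_at_1 = dict(curve.steps)[1]
    assert err_at_k <= err_at_1


def test_min_variables_for_error_scans():
    curve = EliminationCurve(
        steps=((3, 0.3), (2, 0.1), (1, 0.4)), elimination_order=("a", "b", "c")
    )
    assert min_variables_for_error(curve, 0.18) == 2
    assert min_variables_for_error(curve, 0.05) is None
    monotone = EliminationCurve(
        steps=((3, 0.3), (2, 0.2), (1, 0.1)), elimination_order=("a", "b", "c")
    )
    assert min_variables_for_error(monotone, 0.25) == 1
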