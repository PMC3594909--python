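"""The shared classifier contract: fit, scores, rankings, importances."""

import numpy as np
import pytest

from metaboclass import (
    ClassifierSpec,
    FeatureTable,
    SimConfig,
    ValidationError,
    VoteForestClassifier,
    compute_vip,
    fit_classifier,
    generate_dataset,
    mtry,
    predict_class,
    rank_variables,
    scale_gini,
    score_samples,
    svm_rfe,
)

ALL_SPECS = [
    ClassifierSpec("rf", rf_n_trees=100, seed=5),
    ClassifierSpec("pls"),
    ClassifierSpec("lda"),
    ClassifierSpec("svm"),
]


def _table(values, groups):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return FeatureTable(
        values=values,
        sample_ids=[f"s{i}" for i in range(n)],
        variable_ids=[f"v{j:02d}" for j in range(p)],
        groups=groups,
    )


def test_mtry_rule():
    assert mtry(187) == 13
    assert mtry(4) == 2
    assert mtry(1) == 1


def test_forest_oob_error_small_on_separated_data():
    cfg = SimConfig(50, 50, 20, 5, 3.0, 5, 0.3, 5, seed=21)
    table = generate_dataset(cfg)
    model = fit_classifier(ClassifierSpec("rf", seed=3), table)
    assert model.oob_error_ < 0.05


def test_forest_oob_coverage_with_200_trees():
    cfg = SimConfig(50, 50, 10, 0, 0.0, 5, 0.3, 5, seed=22)
    model = fit_classifier(ClassifierSpec("rf", seed=1), generate_dataset(cfg))
    # expected OOB multiplicity per sample is about 200/e ~ 74 trees
    assert model.oob_counts_.min() >= 1
    assert 60 < model.oob_counts_.mean() < 90


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.method)
def test_scores_bounded_and_deterministic(spec, signal_table):
    model = fit_classifier(spec, signal_table)
    scores = score_samples(model, signal_table)
    assert scores.shape == (signal_table.n_samples,)
    assert np.all((scores >= 0) & (scores <= 1))
    model2 = fit_classifier(spec, signal_table)
    assert np.array_equal(scores, score_samples(model2, signal_table))


@pytest.mark.parametrize(
    "spec",
    [
        ClassifierSpec("rf", rf_n_trees=100, seed=5),
        ClassifierSpec("pls", pls_n_components=1),
        ClassifierSpec("lda"),
        ClassifierSpec("svm"),
    ],
    ids=lambda s: s.method,
)
def test_separated_single_variable_orders_classes(spec):
    values = np.concatenate([np.linspace(0, 1, 10), np.linspace(5, 6, 10)])[:, None]
    table = _table(values, ["0"] * 10 + ["1"] * 10)
    model = fit_classifier(spec, table)
    scores = score_samples(model, table)
    assert scores[:10].max() < scores[10:].min()


def test_oob_scores_only_for_forest_on_training_table(signal_table, null_table):
    rf = fit_classifier(ClassifierSpec("rf", rf_n_trees=50, seed=2), signal_table)
    oob = score_samples(rf, signal_table, oob=True)
    assert np.all((oob >= 0) & (oob <= 1))
    with pytest.raises(ValidationError, match="training table"):
        score_samples(rf, null_table, oob=True)
    pls = fit_classifier(ClassifierSpec("pls"), signal_table)
    with pytest.raises(ValidationError, match="rf"):
        score_samples(pls, signal_table, oob=True)


def test_never_oob_sample_raises_helpful_error():
    cfg = SimConfig(10, 10, 5, 0, 0.0, 5, 0.0, 5, seed=9)
    table = generate_dataset(cfg)
    # with only 2 trees some sample is almost surely in-bag for both
    model = fit_classifier(ClassifierSpec("rf", rf_n_trees=2, seed=4), table)
    if np.all(model.oob_counts_ > 0):  # pragma: no cover - improbable draw
        pytest.skip("every sample happened to be OOB")
    with pytest.raises(ValidationError, match="n_trees"):
        model.oob_score_samples()


def test_fit_rejects_degenerate_input():
    X = np.random.default_rng(0).random((6, 3))
    with pytest.raises(ValidationError, match="two classes"):
        ClassifierSpec("svm").build().fit(X, [0] * 6)
    too_small = _table([[1.0], [2.0]], ["0", "1"])
    with pytest.raises(ValidationError, match="3 samples"):
        fit_classifier(ClassifierSpec("lda"), too_small)


def test_predict_class_threshold_conventions():
    assert predict_class([0.2, 0.8]).tolist() == [0, 1]
    assert predict_class([0.5]).tolist() == [0]  # tie goes to class 0
    assert predict_class([1.0, 1.0]).tolist() == [1, 1]
    with pytest.raises(ValidationError, match="threshold"):
        predict_class([0.5], threshold=1.5)


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.method)
def test_rankings_are_reproducible_permutations(spec, signal_table):
    rl = rank_variables(spec, signal_table)
    assert sorted(rl.variable_ids) == sorted(str(v) for v in signal_table.variable_ids)
    assert np.all(np.diff(rl.scores) <= 1e-12)
    rl2 = rank_variables(spec, signal_table)
    assert rl.variable_ids == rl2.variable_ids


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.method)
def test_overwhelming_variable_ranks_first(spec):
    from metaboclass import PreprocessConfig

    cfg = SimConfig(40, 40, 10, 1, 5.0, 5, 0.0, 5, seed=33)
    table = generate_dataset(cfg)
    # importance is compared across variables, so rank on the pretreated scale
    rl = rank_variables(spec, table, preprocess=PreprocessConfig())
    assert rl.variable_ids[0] == "V001"


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------


def test_vip_squares_average_to_one(signal_table):
    model = fit_classifier(ClassifierSpec("pls"), signal_table)
    vip = compute_vip(model)
    assert vip.shape == (signal_table.n_variables,)
    assert abs(np.sum(vip**2) - signal_table.n_variables) < 1e-8


def test_vip_equal_under_symmetric_construction():
    rng = np.random.default_rng(5)
    base = np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)])
    # every variable is the same signal plus nothing: exchangeable columns
    table = _table(np.tile(base[:, None], (1, 6)) + 1e-9, ["0"] * 20 + ["1"] * 20)
    vip = compute_vip(fit_classifier(ClassifierSpec("pls", pls_n_components=1), table))
    assert np.allclose(vip, 1.0, atol=1e-6)


def test_single_informative_variable_attains_max_vip():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(60, 8))
    X[30:, 0] += 4.0
    table = _table(X, ["0"] * 30 + ["1"] * 30)
    vip = compute_vip(fit_classifier(ClassifierSpec("pls", pls_n_components=1), table))
    assert np.argmax(vip) == 0


def test_vip_requires_pls(signal_table):
    lda = fit_classifier(ClassifierSpec("lda"), signal_table)
    with pytest.raises(ValidationError, match="PLS"):
        compute_vip(lda)


# ---------------------------------------------------------------------------
# SVM-RFE / Gini scaling
# ---------------------------------------------------------------------------


def test_svm_rfe_contract(signal_table):
    rl = svm_rfe(signal_table)
    assert len(rl.variable_ids) == signal_table.n_variables
    assert sorted(rl.variable_ids) == sorted(str(v) for v in signal_table.variable_ids)
    assert rl.scores[0] == signal_table.n_variables  # last survivor, reverse order


def test_svm_rfe_keeps_separating_variable_last():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 6))
    X[20:, 2] += 6.0
    table = _table(X, ["0"] * 20 + ["1"] * 20)
    rl = svm_rfe(table)
    assert rl.variable_ids[0] == "v02"


def test_svm_rfe_single_variable():
    table = _table([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]], ["0"] * 3 + ["1"] * 3)
    rl = svm_rfe(table)
    assert rl.variable_ids == ("v00",)


def test_scale_gini_affine_map():
    assert np.allclose(scale_gini([0.0, 0.5, 1.0]), [1.0, 50.5, 100.0])
    assert scale_gini([0.3, 0.9, 0.1]).max() == 100.0
    with pytest.warns(UserWarning, match="equal"):
        assert np.allclose(scale_gini([7.0, 7.0, 7.0]), 100.0)
    with pytest.raises(ValidationError, match="at least one"):
        scale_gini([])


# ---------------------------------------------------------------------------
# forest stability invariants
# ---------------------------------------------------------------------------


def test_forest_oob_error_tracks_kfold_error():
    from metaboclass import kfold_cv

    oob_errors, cv_errors = [], []
    for rep in range(20):
        cfg = SimConfig(100, 100, 30, 6, 1.5, 5, 0.3, 5, seed=700 + rep)
        table = generate_dataset(cfg)
        spec = ClassifierSpec("rf", seed=rep)
        oob_errors.append(fit_classifier(spec, table).oob_error_)
        cv_errors.append(kfold_cv(spec, table, 10, seed=rep).mean_error)
    assert abs(np.mean(oob_errors) - np.mean(cv_errors)) < 0.05


def test_more_trees_do_not_hurt_oob_error(signal_table):
    few, many = [], []
    for rep in range(20):
        few.append(
            fit_classifier(ClassifierSpec("rf", rf_n_trees=50, seed=rep), signal_table).oob_error_
        )
        many.append(
            fit_classifier(ClassifierSpec("rf", rf_n_trees=400, seed=rep), signal_table).oob_error_
        )
    assert np.mean(many) <= np.mean(few) + 0.02


def test_spec_validation_errors():
    with pytest.raises(ValidationError, match="method"):
        ClassifierSpec("boost")
    with pytest.raises(ValidationError, match="rf_n_trees"):
        ClassifierSpec("rf", rf_n_trees=0)
    with pytest.raises(ValidationError, match="svm_c"):
        ClassifierSpec("svm", svm_c=0)


def test_forest_is_plain_sklearn_estimator(signal_table):
    from sklearn.base import clone

    model = VoteForestClassifier(n_trees=30, random_state=0)
    clone(model)  # get_params/set_params round-trip
    model.fit(signal_table.values, signal_table.labels)
    acc = (model.predict(signal_table.values) == signal_table.labels).mean()
    assert acc > 0.9
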