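import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import apcpred as ap

from .conftest import TINY_SVM
from .oracles import concordant_pair_auc


# ---------------------------------------------------------------------------
# stratified folds
# ---------------------------------------------------------------------------


def test_balanced_folds_for_balanced_data():
    labels = np.array([1] * 100 + [-1] * 100)
    assignment = ap.stratified_kfold(labels, k=5, seed=3)
    for fold in range(5):
        mask = assignment == fold
        assert mask.sum() == 40
        assert (labels[mask] == 1).sum() == 20


def test_two_fold_on_four_samples():
    assignment = ap.stratified_kfold(np.array([1, 1, -1, -1]), k=2, seed=0)
    for fold in range(2):
        assert (assignment == fold).sum() == 2


def test_fold_assignment_determinism():
    labels = np.array([1] * 50 + [-1] * 50)
    a = ap.stratified_kfold(labels, k=5, seed=9)
    b = ap.stratified_kfold(labels, k=5, seed=9)
    c = ap.stratified_kfold(labels, k=5, seed=10)
    np.testing.assert_array_equal(a, b)
    assert (a != c).any()


def test_k_larger_than_class_size_errors():
    with pytest.raises(ap.ValidationError, match="class size"):
        ap.stratified_kfold(np.array([1, 1, -1, -1]), k=3, seed=0)


# ---------------------------------------------------------------------------
# threshold-dependent metrics
# ---------------------------------------------------------------------------


def test_perfect_classifier_metrics():
    m = ap.compute_metrics(ap.ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
    assert (m.acc, m.sen, m.spe, m.mcc) == (1.0, 1.0, 1.0, 1.0)


def test_metric_formulas_worked_example():
    m = ap.compute_metrics(ap.ConfusionCounts(tp=40, fn=10, tn=35, fp=15))
    assert m.acc == 0.75
    assert m.sen == 0.8
    assert m.spe == 0.7
    assert math.isclose(m.mcc, 1250 / math.sqrt(45 * 50 * 50 * 55))


def test_mcc_zero_denominator_rule():
    m = ap.compute_metrics(ap.ConfusionCounts(tp=0, fn=10, tn=10, fp=0))
    assert m.sen == 0.0 and m.spe == 1.0 and m.mcc == 0.0


def test_all_zero_counts_error():
    with pytest.raises(ap.ValidationError):
        ap.compute_metrics(ap.ConfusionCounts(0, 0, 0, 0))


def test_metrics_match_formulas_on_random_tables(rng):
    for _ in range(50):
        tp, fp, tn, fn = (int(v) for v in rng.integers(0, 50, size=4))
        if tp + fp + tn + fn == 0:
            continue
        m = ap.compute_metrics(ap.ConfusionCounts(tp, fp, tn, fn))
        assert m.acc == (tp + tn) / (tp + fp + tn + fn)
        assert m.sen == (tp / (tp + fn) if tp + fn else 0.0)
        assert m.spe == (tn / (tn + fp) if tn + fp else 0.0)
        denom = (tn + fn) * (tn + fp) * (tp + fn) * (tp + fp)
        assert m.mcc == ((tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0)
        assert -1.0 <= m.mcc <= 1.0


def test_confusion_counts_from_predictions():
    labels = np.array([1, 1, -1, -1, 1])
    preds = np.array([1, -1, -1, 1, 1])
    c = ap.ConfusionCounts.from_predictions(labels, preds)
    assert (c.tp, c.fn, c.tn, c.fp) == (2, 1, 1, 1)
    assert c.total == 5


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def test_auc_perfect_separation():
    auc, _ = ap.roc_auc([1, 1, -1, -1], [2.0, 3.0, 0.0, 1.0])
    assert auc == 1.0


def test_auc_all_ties_is_half():
    auc, _ = ap.roc_auc([1, 1, -1, -1], [0.5] * 4)
    assert auc == 0.5


def test_auc_three_quarters_example():
    auc, _ = ap.roc_auc([1, 1, -1, -1], [1.0, 3.0, 2.0, 0.0])
    assert auc == 0.75


def test_auc_matches_concordant_pair_count_and_sklearn(rng):
    labels = np.array([1] * 30 + [-1] * 40)
    scores = rng.normal(size=70)
    scores[:10] += 1.0
    auc, _ = ap.roc_auc(labels, scores)
    assert math.isclose(auc, concordant_pair_auc(labels, scores), abs_tol=1e-12)
    assert math.isclose(auc, roc_auc_score(labels == 1, scores), abs_tol=1e-12)


def test_auc_invariant_under_monotone_transform(rng):
    labels = np.array([1] * 25 + [-1] * 25)
    scores = rng.normal(size=50)
    auc1, _ = ap.roc_auc(labels, scores)
    auc2, _ = ap.roc_auc(labels, np.tanh(scores) * 7 + 3)
    assert math.isclose(auc1, auc2, abs_tol=1e-12)


def test_trapezoid_over_roc_points_equals_rank_auc(rng):
    scores = np.round(rng.normal(size=80), 1)  # coarse scores force ties
    labels = np.array([1] * 40 + [-1] * 40)
    auc, points = ap.roc_auc(labels, scores)
    fpr, tpr = np.array(points).T
    assert abs(np.trapezoid(tpr, fpr) - auc) < 1e-12


def test_auc_requires_both_classes_and_finite_scores():
    with pytest.raises(ap.ValidationError):
        ap.roc_auc([1, 1], [0.1, 0.2])
    with pytest.raises(ap.ValidationError):
        ap.roc_auc([1, -1], [np.inf, 0.0])


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------


def test_every_peptide_scored_exactly_once():
    ds = ap.generate(ap.PlantSpec(n_pos=10, n_neg=10, seed=3))
    report = ap.nested_cross_validate(ds, svm=TINY_SVM, seed=4)
    assert sorted(report.samples["id"]) == sorted(ds.ids())
    assert len(report.samples) == 20
    assert report.samples.groupby("fold").size().tolist() == [4] * 5


def test_pooled_counts_equal_sum_of_fold_counts(planted_report):
    total = ap.ConfusionCounts(0, 0, 0, 0)
    for f in planted_report.per_fold:
        total = total + f.counts
    assert total == planted_report.pooled_counts
    assert total.total == 400


def test_pooled_metrics_match_recomputation_from_samples(planted_report):
    df = planted_report.samples
    counts = ap.ConfusionCounts.from_predictions(df["label"].to_numpy(),
                                                 df["prediction"].to_numpy())
    recomputed = ap.compute_metrics(counts)
    assert recomputed.acc == planted_report.pooled.acc
    assert recomputed.mcc == planted_report.pooled.mcc
    auc, _ = ap.roc_auc(df["label"].to_numpy(), df["score"].to_numpy())
    assert math.isclose(auc, planted_report.pooled.auc, abs_tol=1e-12)


def test_chosen_hyperparameters_come_from_the_grid(planted_report):
    for f in planted_report.per_fold:
        assert f.chosen_c in ap.DEFAULT_C_GRID
        assert f.chosen_gamma in ap.DEFAULT_GAMMA_GRID
        assert 0 < f.n_selected_features <= 1600


def test_report_json_is_deterministic():
    ds = ap.generate(ap.PlantSpec(n_pos=20, n_neg=20, seed=8))
    a = ap.nested_cross_validate(ds, svm=TINY_SVM, seed=2).to_json()
    b = ap.nested_cross_validate(ds, svm=TINY_SVM, seed=2).to_json()
    assert a == b


def test_variable_length_dataset_rejected():
    ds = ap.PeptideDataset(
        [ap.Peptide(id="a", sequence="ACDEF", label=ap.Label.POSITIVE),
         ap.Peptide(id="b", sequence="ACDEFG", label=ap.Label.NEGATIVE)]
    )
    with pytest.raises(ap.ValidationError, match="fixed-length"):
        ap.nested_cross_validate(ds, svm=TINY_SVM)


# ---------------------------------------------------------------------------
# final model and prediction
# ---------------------------------------------------------------------------


def test_final_model_generalizes_to_disjoint_split():
    train_ds = ap.generate(ap.PlantSpec(n_pos=150, n_neg=150, seed=21))
    test_ds = ap.generate(ap.PlantSpec(n_pos=60, n_neg=60, seed=22))
    model = ap.train_final_model(train_ds, svm=TINY_SVM, seed=23)
    preds = ap.predict_peptides(model, test_ds)
    truth = np.array([1 if p.label is ap.Label.POSITIVE else -1 for p in test_ds])
    auc, _ = ap.roc_auc(truth, preds["score"].to_numpy())
    assert auc >= 0.90
    assert model.n_selected_features <= 1600


def test_final_model_is_deterministic():
    ds = ap.generate(ap.PlantSpec(n_pos=25, n_neg=25, seed=6))
    cfg = ap.SVMConfig(c_grid=(0.5, 1.0), gamma_grid=(1.0, 2.0), inner_folds=2)
    m1 = ap.train_final_model(ds, svm=cfg, seed=17)
    m2 = ap.train_final_model(ds, svm=cfg, seed=17)
    assert (m1.chosen_c, m1.chosen_gamma) == (m2.chosen_c, m2.chosen_gamma)
    np.testing.assert_array_equal(m1.selection.selected_indices, m2.selection.selected_indices)


def test_predict_rejects_wrong_window():
    ds = ap.generate(ap.PlantSpec(n_pos=25, n_neg=25, seed=6))
    model = ap.train_final_model(ds, svm=TINY_SVM, seed=1)
    short = ap.PeptideDataset([ap.Peptide(id="s", sequence="ACDEF")])
    with pytest.raises(ap.ValidationError, match="window"):
        ap.predict_peptides(model, short)


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------


def test_sweep_cartesian_row_count(small_planted_dataset):
    df = ap.parameter_sweep(small_planted_dataset, I_values=[2, 3], p_values=[0.5, 1.0],
                            svm=TINY_SVM, seed=0)
    assert len(df) == 4
    assert df["error"].eq("").all()
    assert set(zip(df["max_gap"], df["p_cutoff"])) == {(2, 0.5), (2, 1.0), (3, 0.5), (3, 1.0)}


def test_sweep_window_sizes_and_feature_counts(small_planted_dataset):
    df = ap.parameter_sweep(small_planted_dataset, I_values=[1], p_values=[1.0],
                            window_sizes=[12, 16, 20], svm=TINY_SVM, seed=0)
    assert len(df) == 3
    assert df["window"].tolist() == [12, 16, 20]
    assert df["n_features_total"].tolist() == [800, 800, 800]
    assert df["n_features_selected_mean"].tolist() == [800.0, 800.0, 800.0]


def test_crop_dataset_symmetric_with_c_terminal_extra():
    assert ap.crop_dataset(
        ap.PeptideDataset([ap.Peptide(id="a", sequence="ACDEFGHIK", label=ap.Label.POSITIVE)]),
        4,
    )[0].sequence == "DEFG"  # excess 5: 2 cut N-terminal, 3 cut C-terminal


def test_sweep_continues_past_failures(small_planted_dataset):
    # p cutoff so small that selection is empty -> row marked, sweep continues
    df = ap.parameter_sweep(small_planted_dataset, I_values=[1], p_values=[1e-300, 1.0],
                            svm=TINY_SVM, seed=0)
    assert len(df) == 2
    assert df.iloc[0]["error"] != ""
    assert df.iloc[1]["error"] == ""
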