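"""Cohort scoring: confusion metrics, MCC/AUC oracles, model selection, LOO."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from pesig import io, preprocess, synthetic as syn
from pesig.evaluate import (
    MissingFeatureError,
    loo_gene_importance,
    mcc_from_counts,
    predict,
    rank_auc,
    report_from_class_accuracies,
    score,
    select_best,
)
from pesig.signature import forward_select

from conftest import separable_training


@pytest.fixture(scope="module")
def planted_model():
    matrix, labels = separable_training(
        n_informative=2, n_noise=4, gap_sd=4.0, seed=20
    )
    model = forward_select(
        matrix.feature_ids, matrix, labels, C=100.0, sigma=10.0, seed=1
    )
    return model, matrix, labels


class TestPredict:
    def test_training_matrix_reproduces_training_labels(self, planted_model):
        model, matrix, labels = planted_model
        pred = predict(model, matrix)
        assert (pred["label"].to_numpy() == labels.to_numpy()).all()

    def test_duplicated_sample_column_identical_predictions(self, planted_model):
        model, matrix, _ = planted_model
        dup = matrix.data.copy()
        dup["COPY"] = dup[matrix.sample_ids[0]]
        pred = predict(model, io.ExpressionMatrix(dup))
        assert pred.loc["COPY", "label"] == pred.loc[matrix.sample_ids[0], "label"]
        assert pred.loc["COPY", "decision_value"] == pytest.approx(
            pred.loc[matrix.sample_ids[0], "decision_value"]
        )

    def test_missing_feature_error_lists_gene(self, planted_model):
        model, matrix, _ = planted_model
        reduced = io.ExpressionMatrix(matrix.data.drop(index=model.features[0]))
        with pytest.raises(MissingFeatureError, match=model.features[0]):
            predict(model, reduced)

    def test_nan_expression_rejected(self, planted_model):
        model, matrix, _ = planted_model
        broken = matrix.data.copy()
        broken.loc[model.features[0], matrix.sample_ids[0]] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            predict(model, io.ExpressionMatrix(broken))


class TestScore:
    def test_published_gefitinib_row_counts(self):
        # 10 sensitive all correct, 2 resistant half correct
        rep = report_from_class_accuracies(10, 2, 1.0, 0.5)
        assert round(rep.mcc, 2) == 0.67

    def test_published_sunitinib_row_counts(self):
        rep = report_from_class_accuracies(6, 12, 0.67, 0.92)
        assert round(rep.mcc, 2) == 0.61
        assert rep.rounded()["overall"] == 83

    def test_perfect_predictions(self):
        truth = [io.RESISTANT] * 3 + [io.SENSITIVE] * 5
        rep = score(np.array(truth), truth)
        assert rep.mcc == 1.0 and rep.overall_acc == 1.0

    def test_single_class_prediction_mcc_zero_by_convention(self):
        truth = [io.RESISTANT] * 3 + [io.SENSITIVE] * 5
        rep = score(np.full(8, io.RESISTANT), truth)
        assert rep.mcc == 0.0

    def test_overall_accuracy_identity(self):
        rng = np.random.default_rng(0)
        truth = rng.choice([io.SENSITIVE, io.RESISTANT], 50)
        pred = rng.choice([io.SENSITIVE, io.RESISTANT], 50)
        rep = score(pred, truth)
        assert rep.tp + rep.fn == int((truth == io.RESISTANT).sum())
        assert rep.tn + rep.fp == int((truth == io.SENSITIVE).sum())
        assert rep.overall_acc == (rep.tp + rep.tn) / 50

    def test_mcc_against_brute_force_tally_1000_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            tp, fn, tn, fp = rng.integers(0, 20, size=4)
            if tp + fn + tn + fp == 0:
                continue
            truth = np.array(
                [io.RESISTANT] * (tp + fn) + [io.SENSITIVE] * (tn + fp)
            )
            pred = np.array(
                [io.RESISTANT] * tp + [io.SENSITIVE] * fn
                + [io.SENSITIVE] * tn + [io.RESISTANT] * fp
            )
            rep = score(pred, truth)
            assert rep.mcc == pytest.approx(
                mcc_from_counts(tp, fn, tn, fp), abs=1e-12
            )
            # independent route: sklearn's per-sample implementation
            assert rep.mcc == pytest.approx(
                matthews_corrcoef(truth, pred), abs=1e-9
            )

    def test_mcc_symmetry_under_class_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            truth = rng.choice([io.SENSITIVE, io.RESISTANT], 30)
            pred = rng.choice([io.SENSITIVE, io.RESISTANT], 30)
            if len(set(truth)) < 2:
                continue
            a = score(pred, truth).mcc
            b = score(-pred, -truth).mcc
            assert abs(a) == pytest.approx(abs(b), abs=1e-12)

    def test_single_class_subset_rounds_without_error(self):
        # a consensus subset may contain only resistant samples; the
        # undefined sensitive-class accuracy must surface as NaN, not crash
        truth = [io.RESISTANT] * 4
        rep = score(np.full(4, io.RESISTANT), truth)
        rounded = rep.rounded()
        assert np.isnan(rounded["sensitive"])
        assert rounded["resistant"] == 100 and rounded["overall"] == 100

    def test_group_subreports(self):
        truth = pd.Series([io.RESISTANT, io.RESISTANT, io.SENSITIVE, io.SENSITIVE])
        pred = np.array([io.RESISTANT, io.SENSITIVE, io.SENSITIVE, io.RESISTANT])
        groups = pd.Series(["F", "M", "F", "M"])
        rep = score(pred, truth, groups=groups)
        assert set(rep.group_reports) == {"F", "M"}
        assert rep.group_reports["F"].overall_acc == 1.0
        assert rep.group_reports["M"].overall_acc == 0.0


class TestAuc:
    def test_perfect_and_inverted_ranking(self):
        truth = np.array([io.RESISTANT] * 3 + [io.SENSITIVE] * 4)
        assert rank_auc(np.array([5, 4, 3, 2, 1, 0, -1]), truth) == 1.0
        assert rank_auc(np.array([-1, 0, 1, 2, 3, 4, 5]), truth) == 0.0

    def test_random_ranking_near_half(self):
        rng = np.random.default_rng(7)
        truth = np.array([io.RESISTANT] * 100 + [io.SENSITIVE] * 100)
        aucs = [rank_auc(rng.normal(size=200), truth) for _ in range(20)]
        assert abs(float(np.mean(aucs)) - 0.5) < 0.1

    def test_midrank_ties_match_sklearn(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            truth = rng.choice([io.SENSITIVE, io.RESISTANT], 40)
            if len(set(truth)) < 2:
                continue
            scores = rng.integers(0, 5, size=40).astype(float)  # heavy ties
            assert rank_auc(scores, truth) == pytest.approx(
                roc_auc_score(truth == io.RESISTANT, scores), abs=1e-12
            )


class TestSelectBest:
    def test_highest_mcc_wins(self):
        reports = {"a": _fake_report(0.2, 0.6), "b": _fake_report(0.7, 0.6),
                   "c": _fake_report(0.5, 0.9)}
        assert select_best(reports) == "b"

    def test_mcc_tie_broken_by_overall_accuracy(self):
        reports = {"a": _fake_report(0.5, 0.6), "b": _fake_report(0.5, 0.8)}
        assert select_best(reports) == "b"

    def test_single_model(self):
        assert select_best({"only": _fake_report(0.1, 0.5)}) == "only"


def _fake_report(mcc, oa):
    from pesig.evaluate import ValidationReport

    return ValidationReport(
        tp=1, fn=1, tn=1, fp=1, sensitive_acc=oa, resistant_acc=oa,
        overall_acc=oa, mcc=mcc, auc=0.5,
    )


@pytest.fixture(scope="module")
def loo_setup():
    spec = syn.SyntheticSpec(
        n_cell_lines=40, n_patients=32, n_genes=30,
        n_planted_angle_genes=4, n_curated=2, n_cn_correlated=0,
        effect_size=2.5, seed=21,
    )
    panel = syn.make_cell_line_panel(spec)
    labels, _ = preprocess.dichotomize_gi50(panel.responses)
    # a 2-gene model: one informative planted gene + one pure-noise gene
    genes = [list(panel.planted)[0], panel.noise_genes[0]]
    x = panel.expression
    from pesig.signature import _design, _fit_svc
    from pesig.signature import SignatureModel, cv_criterion

    clf = _fit_svc(_design(x, genes), labels.to_numpy(), 100.0, 10.0)
    model = SignatureModel(
        features=genes, C=100.0, sigma=10.0, criterion="misclassification",
        criterion_value=cv_criterion(genes, x, labels, 100.0, 10.0),
        support_vectors=clf.support_vectors_, dual_coef=clf.dual_coef_[0],
        intercept=float(clf.intercept_[0]), gamma=1 / (2 * 10.0**2),
    )
    cohort = syn.make_patient_cohort(spec, {genes[0]: panel.planted[genes[0]]})
    test_matrix = preprocess.quantile_normalize(
        preprocess.collapse_probes(cohort.expression), x, interpolate=True
    )
    return model, x, labels, test_matrix, cohort.responses.label


class TestLooGeneImportance:
    def test_removing_noise_gene_small_effect(self, loo_setup):
        model, x, labels, tm, truth = loo_setup
        deltas = loo_gene_importance(model, x, labels, tm, truth, seed=0)
        noise_gene = model.features[1]
        assert abs(deltas.loc[noise_gene, "delta_mcc"]) < 0.25

    def test_removing_informative_gene_drops_to_majority(self, loo_setup):
        model, x, labels, tm, truth = loo_setup
        deltas = loo_gene_importance(model, x, labels, tm, truth, seed=0)
        informative = model.features[0]
        base = score(predict(model, tm), truth).overall_acc
        majority = max((truth == io.RESISTANT).mean(), (truth == io.SENSITIVE).mean())
        degraded = base + deltas.loc[informative, "delta_overall_acc"]
        assert degraded <= majority + 0.15

    def test_single_feature_model_rejected(self, loo_setup):
        model, x, labels, tm, truth = loo_setup
        from dataclasses import replace

        one = replace(model, features=[model.features[0]])
        with pytest.raises(ValueError, match=">=2"):
            loo_gene_importance(one, x, labels, tm, truth)

    def test_false_positive_flag_semantics(self, loo_setup):
        model, x, labels, tm, truth = loo_setup
        deltas = loo_gene_importance(model, x, labels, tm, truth, seed=0)
        for gene, row in deltas.iterrows():
            assert row["candidate_false_positive"] == (row["delta_mcc"] > 0)
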