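"""Evaluation protocol: macro-F1, holdout, cross-validation, support trend, PCA."""

import numpy as np
import pandas as pd
import pytest

from crfmap import (
    Corpus,
    FieldRecord,
    SynthConfig,
    cross_validate,
    evaluate_holdout,
    evaluate_split,
    generate_corpus,
    macro_f1,
    pca_project,
    support_accuracy_table,
)
from crfmap.evaluation import MODES


def macro_f1_oracle(truth, pred):
    """Independent confusion-matrix computation of macro-F1."""
    scores = []
    for cls in sorted(set(truth)):
        tp = sum(1 for t, p in zip(truth, pred) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(truth, pred) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(truth, pred) if t == cls and p != cls)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        scores.append(
            2 * precision * recall / (precision + recall) if precision + recall else 0.0
        )
    return sum(scores) / len(scores)


class TestMacroF1:
    def test_perfect_predictions(self):
        assert macro_f1(["A", "B", "C"], ["A", "B", "C"]) == 1.0

    def test_worked_two_class_example(self):
        assert macro_f1(list("AABB"), list("ABAB")) == pytest.approx(0.5)

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(0)
        classes = list("ABCDE")
        for _ in range(100):
            n = int(rng.integers(5, 60))
            truth = [classes[i] for i in rng.integers(0, 5, n)]
            pred = [classes[i] for i in rng.integers(0, 5, n)]
            assert macro_f1(truth, pred) == pytest.approx(
                macro_f1_oracle(truth, pred), abs=1e-12
            )

    def test_only_truth_classes_averaged(self):
        # predictions invent class C; averaging stays over {A, B}
        assert macro_f1(list("AABB"), list("AACC")) == pytest.approx(
            macro_f1_oracle(list("AABB"), list("AACC"))
        )

    def test_empty_or_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            macro_f1([], [])
        with pytest.raises(ValueError):
            macro_f1(["A"], ["A", "B"])


class TestEvaluateHoldout:
    def test_mode_dominance(self, balanced_report):
        acc = balanced_report.accuracy
        assert acc["contains"] >= acc["nearest"]
        assert acc["contains"] >= acc["majority"]

    def test_end_to_end_determinism(self, small_corpus):
        r1 = evaluate_holdout(small_corpus.corpus, seed=2, n_same=5, n_diff=5)
        r2 = evaluate_holdout(small_corpus.corpus, seed=2, n_same=5, n_diff=5)
        assert r1.accuracy == r2.accuracy
        assert r1.macro_f1 == r2.macro_f1
        pd.testing.assert_frame_equal(r1.per_class, r2.per_class)

    def test_per_class_accuracies_average_to_overall(self, balanced_report):
        pc = balanced_report.per_class
        weighted = (pc["accuracy"] * pc["test_count"]).sum() / pc["test_count"].sum()
        assert weighted == pytest.approx(balanced_report.accuracy["nearest"])

    def test_unseen_label_counts_as_miss_and_is_flagged(self, small_corpus):
        # train lacks label Z entirely; its test records must miss in all modes
        extra = [
            FieldRecord("ZQF", "ZQX", "entirely novel prompt words", "", "ZZTEST")
            for _ in range(2)
        ]
        train = Corpus(list(small_corpus.corpus.records))
        test = Corpus(list(small_corpus.corpus.records[:10]) + extra)
        report = evaluate_split(train, test, n_same=5, n_diff=5, seed=0)
        row = report.per_class.set_index("label").loc["ZZTEST"]
        assert bool(row["unseen_in_train"])
        assert row["accuracy"] == 0.0


class TestCrossValidate:
    def test_partition_and_inherited_dominance(self):
        gt = generate_corpus(SynthConfig(n_classes=4, support=25, seed=8))
        reports = cross_validate(gt.corpus, folds=5, seed=8, n_same=4, n_diff=4)
        assert sum(r.n_test for r in reports) == len(gt.corpus)
        for r in reports:
            assert r.accuracy["contains"] >= r.accuracy["nearest"]
            assert r.accuracy["contains"] >= r.accuracy["majority"]

    def test_mean_fold_accuracy_consistent_with_holdout(self):
        gt = generate_corpus(SynthConfig(n_classes=4, support=25, seed=8))
        reports = cross_validate(gt.corpus, folds=5, seed=8, n_same=4, n_diff=4)
        holdout = evaluate_holdout(gt.corpus, seed=8, n_same=4, n_diff=4)
        mean_cv = np.mean([r.accuracy["nearest"] for r in reports])
        assert abs(mean_cv - holdout.accuracy["nearest"]) <= 0.1

    def test_folds_below_two_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            cross_validate(small_corpus.corpus, folds=1)


class TestSupportAccuracyTable:
    def _report_with(self, rows):
        from crfmap.evaluation import EvalReport

        return EvalReport(
            accuracy={m: 0.0 for m in MODES},
            macro_f1={m: 0.0 for m in MODES},
            per_class=pd.DataFrame(rows),
            n_train=0,
            n_test=0,
            train_pair_accuracy=1.0,
            seed=0,
            config={},
            history=[],
        )

    def test_group_means_split_at_threshold(self):
        rows = [
            {"label": "A", "train_support": 10, "test_count": 5, "accuracy": 0.2},
            {"label": "B", "train_support": 50, "test_count": 5, "accuracy": 0.6},
            {"label": "C", "train_support": 200, "test_count": 5, "accuracy": 1.0},
        ]
        out = support_accuracy_table(self._report_with(rows), threshold=100)
        assert out["mean_accuracy_below"] == pytest.approx(0.4)
        assert out["mean_accuracy_at_or_above"] == pytest.approx(1.0)

    def test_degenerate_single_group(self):
        rows = [
            {"label": "A", "train_support": 50, "test_count": 5, "accuracy": 0.5},
            {"label": "B", "train_support": 50, "test_count": 5, "accuracy": 0.7},
        ]
        out = support_accuracy_table(self._report_with(rows), threshold=100)
        assert np.isnan(out["mean_accuracy_at_or_above"])
        assert out["mean_accuracy_below"] == pytest.approx(0.6)

    def test_threshold_zero_equals_overall_mean(self):
        rows = [
            {"label": "A", "train_support": 10, "test_count": 5, "accuracy": 0.4},
            {"label": "B", "train_support": 20, "test_count": 5, "accuracy": 0.8},
        ]
        out = support_accuracy_table(self._report_with(rows), threshold=0)
        assert out["mean_accuracy_at_or_above"] == pytest.approx(0.6)
        assert np.isnan(out["mean_accuracy_below"])


class TestPcaProject:
    def test_rank_two_data_reconstructs_exactly(self):
        rng = np.random.default_rng(2)
        basis = rng.normal(size=(2, 32))
        coords = rng.normal(size=(100, 2))
        X = coords @ basis + rng.normal(size=32)  # plane + offset
        scores = pca_project(X, dims=2)
        # reconstruction through the two components recovers centered data
        Xc = X - X.mean(axis=0)
        proj = scores @ np.linalg.pinv(scores) @ Xc
        np.testing.assert_allclose(proj, Xc, atol=1e-9)

    def test_component_variance_ordering(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 8)) * np.array([5, 3, 1, 1, 1, 1, 1, 1])
        scores = pca_project(X, dims=2)
        assert scores[:, 0].var() >= scores[:, 1].var()

    def test_matches_eigendecomposition_oracle_up_to_sign(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 6))
        scores = pca_project(X, dims=3)
        Xc = X - X.mean(axis=0)
        w, v = np.linalg.eigh(np.cov(Xc.T))
        order = np.argsort(w)[::-1][:3]
        oracle = Xc @ v[:, order]
        for j in range(3):
            assert np.allclose(scores[:, j], oracle[:, j], atol=1e-8) or np.allclose(
                scores[:, j], -oracle[:, j], atol=1e-8
            )

    def test_insufficient_vectors_rejected(self):
        with pytest.raises(ValueError):
            pca_project(np.zeros((2, 5)), dims=2)
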