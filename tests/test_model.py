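"""ROC/AUC, classification metrics, LOO and split protocols, pipelines."""

import numpy as np
import pytest

from dsaflow.model import (
    ModelConfig,
    classification_metrics,
    loo_cv,
    permutation_null_auc,
    roc_auc,
    run_grading_pipeline,
    split_evaluate,
)


def auc_pair_count_oracle(scores, labels):
    """Exhaustive concordant/tied pair counting."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


FAST = ModelConfig(n_boot=200, isr_k=5, c_grid=(1.0,))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_worked_four_case_value(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_all_tied_scores(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_exhaustive_pair_counting(self):
        """Rank formulation equals brute-force pair counting for n <= 12."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.integers(0, 5, n) / 4.0  # coarse grid forces ties
            assert roc_auc(scores, labels) == pytest.approx(
                auc_pair_count_oracle(scores, labels), abs=1e-12
            )

    def test_inverted_scores_mirror_auc(self, rng):
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        assert roc_auc(-scores, labels) == pytest.approx(
            1.0 - roc_auc(scores, labels)
        )

    def test_equals_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores)
        )


class TestClassificationMetrics:
    def test_worked_confusion_counts(self):
        # TP 9, FN 1, TN 8, FP 2
        labels = [1] * 10 + [0] * 10
        predicted = [1] * 9 + [0] + [0] * 8 + [1] * 2
        scores = [float(p) for p in predicted]
        m = classification_metrics(predicted, scores, labels, n_boot=100, seed=0)
        assert m.sens == pytest.approx(0.9)
        assert m.spec == pytest.approx(0.8)
        assert m.acc == pytest.approx(0.85)

    def test_perfect_prediction(self):
        labels = [0, 0, 1, 1]
        m = classification_metrics(labels, [0.0, 0.0, 1.0, 1.0], labels,
                                   n_boot=100, seed=0)
        assert (m.acc, m.sens, m.spec, m.auc) == (1.0, 1.0, 1.0, 1.0)
        assert m.auc_ci == (1.0, 1.0)

    def test_ci_brackets_auc(self, rng):
        scores = rng.normal(size=40) + np.repeat([0, 1], 20)
        labels = np.repeat([0, 1], 20)
        m = classification_metrics(scores > 0.5, scores, labels,
                                   n_boot=500, seed=1)
        assert m.auc_ci[0] <= m.auc <= m.auc_ci[1]


class TestLooCv:
    def test_separable_clusters_perfect_auc(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 5))
        y = np.repeat([0, 1], 30)
        X[y == 1] += 3.0  # 3 sd separation
        m, scores = loo_cv(X, y, FAST, seed=0)
        assert m.auc == 1.0
        assert len(scores) == 60

    def test_permuted_labels_near_chance(self):
        aucs = permutation_null_auc(
            np.random.default_rng(1).normal(size=(40, 6)),
            np.repeat([0, 1], 20), FAST, n_permutations=3, seed=0,
        )
        assert abs(np.mean(aucs) - 0.5) <= 0.15

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            loo_cv(np.zeros((3, 2)), [0, 1, 1], FAST)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 8))
        y = np.repeat([0, 1], 10)
        m1, s1 = loo_cv(X, y, FAST, seed=3)
        m2, s2 = loo_cv(X, y, FAST, seed=3)
        np.testing.assert_array_equal(s1, s2)
        assert m1 == m2

    def test_leakage_canary(self):
        """A label-copy feature gives AUC ~1; permuting labels kills it.

        This guards the in-fold selection/fit discipline: if selection or
        standardization saw the held-out case, the permuted canary would
        stay optimistically high.
        """
        rng = np.random.default_rng(4)
        n = 40
        y = np.repeat([0, 1], 20)
        X = rng.normal(size=(n, 21))
        X[:, 0] = y  # canary column
        cfg = ModelConfig(n_boot=100, isr_k=5, c_grid=(1.0,), n_features=5)
        m, _ = loo_cv(X, y, cfg, seed=0)
        assert m.auc >= 0.95

        y_perm = rng.permutation(y)
        m_perm, _ = loo_cv(X, y_perm, cfg, seed=0)
        assert m_perm.auc <= 0.7

    def test_cohort_scope_selection_runs_and_flags_bias(self):
        """selection_scope='cohort' selects once on all cases (biased)."""
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 15)
        X = rng.normal(size=(30, 40))
        X[y == 1, :2] += 1.5
        cfg = ModelConfig(n_boot=100, isr_k=5, c_grid=(1.0,), n_features=5)
        m, scores = loo_cv(X, y, cfg, seed=0, selection_scope="cohort")
        assert len(scores) == 30 and 0.0 <= m.auc <= 1.0
        with pytest.raises(ValueError, match="selection_scope"):
            loo_cv(X, y, cfg, seed=0, selection_scope="all")


class TestSplitEvaluate:
    def test_stratified_three_seven_split(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 4))
        y = np.repeat([0, 1], 50)
        X[y == 1] += 3.0
        cv_m, test_m = split_evaluate(X, y, FAST, test_fraction=0.3, seed=0)
        assert test_m.n_pos + test_m.n_neg == 30
        assert abs(test_m.n_pos - 15) <= 1  # class ratio preserved to +-1
        assert cv_m.auc == 1.0 and test_m.auc == 1.0

    def test_same_seed_same_partitions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        y = np.repeat([0, 1], 20)
        a = split_evaluate(X, y, FAST, seed=5)
        b = split_evaluate(X, y, FAST, seed=5)
        assert a == b

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_evaluate(np.zeros((10, 2)), np.repeat([0, 1], 5),
                           FAST, test_fraction=0.0)


class TestPipelines:
    def test_diagnosis_pipeline_report_structure(self, small_cohort_dir):
        from dsaflow.model import run_diagnosis_pipeline

        rep = run_diagnosis_pipeline(small_cohort_dir, "temporal", FAST, seed=0)
        assert rep["task"] == "diagnosis"
        assert rep["n_cases"] == 12 and rep["n_avm"] == 6
        assert 0.0 <= rep["loo"]["auc"] <= 1.0
        assert len(rep["loo_scores"]) == 12

    def test_temporal_features_separate_phantom_groups(self, small_cohort_dir):
        """T1-T5 are (1,...,1) vs (0,...,0) by construction -> AUC ~ 1."""
        from dsaflow.model import run_diagnosis_pipeline

        rep = run_diagnosis_pipeline(small_cohort_dir, "temporal", FAST, seed=0)
        assert rep["loo"]["auc"] >= 0.95

    def test_grading_needs_both_grades(self, tmp_path):
        from dsaflow import phantom

        phantom.generate_cohort(6, 1.0, 0.0, 2, tmp_path / "lowonly",
                                noise_sd=0.0)
        with pytest.raises(ValueError, match="high"):
            run_grading_pipeline(tmp_path / "lowonly", FAST, seed=0)

    def test_grading_report_structure(self, small_cohort_dir):
        rep = run_grading_pipeline(small_cohort_dir, FAST, seed=0)
        assert rep["n_cases"] == 6 and rep["n_high"] == 3
        assert set(rep) >= {"combined", "radiomics"}
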