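import numpy as np
import pytest

import somnowave as sw
from somnowave.evaluation import ConfusionMatrix
from somnowave.stages import STAGES
from somnowave.study_tables import (
    HEALTHY_UNBALANCED_ROW_PERCENT,
    INSOMNIA_BALANCED_ROW_PERCENT,
    INSOMNIA_BALANCED_ROW_TOTAL,
    UNBALANCED_COUNTS,
)


def insomnia_balanced_cm():
    return ConfusionMatrix.from_row_percent(
        INSOMNIA_BALANCED_ROW_PERCENT, [INSOMNIA_BALANCED_ROW_TOTAL] * 6
    )


def healthy_unbalanced_cm():
    totals = [UNBALANCED_COUNTS["healthy"][s] for s in STAGES]
    return ConfusionMatrix.from_row_percent(HEALTHY_UNBALANCED_ROW_PERCENT, totals)


class TestConfusionMatrix:
    def test_from_predictions_perfect(self):
        y = [s for s in STAGES for _ in range(3)]
        cm = ConfusionMatrix.from_predictions(y, y)
        assert np.trace(cm.counts) == len(y)
        np.testing.assert_allclose(np.diag(cm.row_percent()), 100.0)

    def test_constant_predictor_fills_first_column(self):
        y = [s for s in STAGES for _ in range(2)]
        cm = ConfusionMatrix.from_predictions(y, ["W"] * len(y))
        assert cm.counts[:, 0].sum() == len(y)
        np.testing.assert_allclose(cm.row_percent()[:, 0], 100.0)

    def test_counts_conserve_samples(self, rng):
        y_true = [STAGES[i] for i in rng.integers(0, 6, 200)]
        y_pred = [STAGES[i] for i in rng.integers(0, 6, 200)]
        assert ConfusionMatrix.from_predictions(y_true, y_pred).total == 200

    def test_row_percent_rows_sum_to_100(self):
        cm = healthy_unbalanced_cm()
        np.testing.assert_allclose(cm.row_percent().sum(axis=1), 100.0, atol=0.5)


class TestOverallAccuracy:
    def test_balanced_insomnia_table(self):
        assert sw.overall_accuracy(insomnia_balanced_cm()) == pytest.approx(92.8, abs=0.05)

    def test_identity_is_100(self):
        assert sw.overall_accuracy(ConfusionMatrix(np.eye(6, dtype=int) * 7)) == 100.0

    def test_uniform_matrix_is_chance(self):
        cm = ConfusionMatrix(np.full((6, 6), 10))
        assert sw.overall_accuracy(cm) == pytest.approx(100.0 / 6)

    def test_equals_weighted_mean_of_diagonal_row_percent(self, rng):
        counts = rng.integers(0, 30, (6, 6))
        cm = ConfusionMatrix(counts)
        rows = counts.sum(axis=1)
        weighted = np.sum(np.diag(cm.row_percent()) * rows) / rows.sum()
        assert sw.overall_accuracy(cm) == pytest.approx(weighted)


class TestPerClassOvr:
    def test_healthy_wake_reconstruction(self):
        """One-vs-rest reading reproduces the reported 95.84% wake accuracy
        within the rounding of the printed percent table."""
        acc = sw.per_class_ovr_accuracy(healthy_unbalanced_cm(), "W")
        assert acc == pytest.approx(95.84, abs=0.15)

    def test_perfect_matrix(self):
        cm = ConfusionMatrix(np.eye(6, dtype=int) * 5)
        for s in STAGES:
            assert sw.per_class_ovr_accuracy(cm, s) == 100.0

    def test_absent_never_predicted_class_is_degenerate_100(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0, 0] = 10  # only W present and predicted
        assert sw.per_class_ovr_accuracy(ConfusionMatrix(counts), "S3") == 100.0


class TestF1:
    def test_balanced_insomnia_rem(self):
        f1 = sw.f1_per_class(insomnia_balanced_cm(), "REM")
        assert round(f1, 2) == 0.93

    def test_perfect_is_one(self):
        cm = ConfusionMatrix(np.eye(6, dtype=int) * 4)
        assert sw.f1_per_class(cm, "S2") == 1.0

    def test_never_predicted_is_zero(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[1, 0] = 5  # S1 always predicted W
        counts[0, 0] = 5
        assert sw.f1_per_class(ConfusionMatrix(counts), "S1") == 0.0


class TestKappa:
    def test_perfect_diagonal(self):
        assert sw.cohens_kappa(ConfusionMatrix(np.eye(6, dtype=int) * 9)) == 1.0

    def test_independent_outer_product_is_zero(self):
        row = np.array([1, 2, 3, 4, 5, 6])
        col = np.array([6, 5, 4, 3, 2, 1])
        cm = ConfusionMatrix(np.outer(row, col))
        assert sw.cohens_kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_balanced_insomnia_reconstruction(self):
        assert sw.cohens_kappa(insomnia_balanced_cm()) == pytest.approx(0.9145, abs=0.005)

    def test_uniform_truth_gives_pe_one_sixth(self):
        cm = insomnia_balanced_cm()
        counts = cm.counts.astype(float)
        p_e = counts.sum(axis=1) @ counts.sum(axis=0) / cm.total**2
        assert p_e == pytest.approx(1.0 / 6.0, abs=1e-3)

    def test_kappa_below_accuracy_proportion(self, rng):
        for _ in range(20):
            cm = ConfusionMatrix(rng.integers(0, 40, (6, 6)))
            assert sw.cohens_kappa(cm) <= sw.overall_accuracy(cm) / 100 + 1e-12

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        y1 = [STAGES[i] for i in rng.integers(0, 6, 300)]
        y2 = [STAGES[i] for i in rng.integers(0, 6, 300)]
        cm = ConfusionMatrix.from_predictions(y1, y2)
        assert sw.cohens_kappa(cm) == pytest.approx(
            cohen_kappa_score(y1, y2), abs=1e-12
        )


class TestAggregation:
    def test_reported_trial_aggregation_uses_population_std(self):
        from somnowave.study_tables import HEALTHY_COMBINED_TRIALS

        mean, std = sw.aggregate_trials(HEALTHY_COMBINED_TRIALS)
        assert round(mean, 1) == 78.3
        assert round(std, 2) == 1.21
        # the sample std would *not* reproduce the printed spread
        assert np.std(HEALTHY_COMBINED_TRIALS, ddof=1) == pytest.approx(1.35, abs=0.01)


class TestMajorityBaseline:
    def test_constant_majority_prediction_on_unbalanced_healthy(self):
        counts = UNBALANCED_COUNTS["healthy"]
        y_true = [s for s in STAGES for _ in range(counts[s])]
        cm = ConfusionMatrix.from_predictions(y_true, ["S2"] * len(y_true))
        assert sw.overall_accuracy(cm) == pytest.approx(100.0 * 2172 / 6063, abs=1e-9)


class TestRoc:
    def test_perfect_separation(self):
        y = ["W"] * 5 + ["S1"] * 5
        scores = np.zeros((10, 6))
        scores[:5, 0] = 1.0
        scores[5:, 1] = 1.0
        roc = sw.roc_ovr(scores, y)
        assert roc["W"]["auc"] == 1.0
        assert roc["S1"]["auc"] == 1.0

    def test_monotone_transform_invariance(self, rng):
        y = [STAGES[i] for i in rng.integers(0, 3, 60)]
        scores = rng.random((60, 6))
        a = sw.roc_ovr(scores, y)
        b = sw.roc_ovr(np.exp(3 * scores), y)
        for s in a:
            assert a[s]["auc"] == pytest.approx(b[s]["auc"], abs=1e-12)

    def test_label_permutation_gives_chance_auc(self, rng):
        scores = rng.random((300, 6))
        aucs = []
        for _ in range(20):
            y = [STAGES[i] for i in rng.integers(0, 6, 300)]
            roc = sw.roc_ovr(scores, y)
            aucs.extend(d["auc"] for d in roc.values())
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


class TestRepeatedCV:
    def test_small_class_rejected_with_guidance(self, rng):
        X = rng.standard_normal((30, 2))
        y = ["W"] * 25 + ["S1"] * 5
        with pytest.raises(ValueError, match="fewer than k"):
            sw.repeated_cv(X, y, k=10, trials=1)

    def test_deterministic_and_stratified(self, stage_Xy):
        X, y = stage_Xy
        a = sw.repeated_cv(X, y, n_learners=5, k=5, trials=2, seed=4)
        b = sw.repeated_cv(X, y, n_learners=5, k=5, trials=2, seed=4)
        assert a.per_trial_accuracy == b.per_trial_accuracy
        assert a.per_trial_kappa == b.per_trial_kappa
        assert a.confusion.total == len(y) * 2  # pooled over trials

    def test_aggregates_are_population_std(self, stage_Xy):
        X, y = stage_Xy
        res = sw.repeated_cv(X, y, n_learners=5, k=5, trials=3, seed=0)
        assert res.std_accuracy == pytest.approx(
            np.std(res.per_trial_accuracy, ddof=0)
        )
        assert res.kappa_error == pytest.approx(np.std(res.per_trial_kappa, ddof=0))

    def test_strict_train_balancing_runs(self, stage_Xy):
        X, y = stage_Xy
        res = sw.repeated_cv(X, y, n_learners=5, k=5, trials=1, seed=0,
                             train_balance_target=30)
        assert 0.0 <= res.mean_accuracy <= 100.0


def test_stratified_fold_proportions(stage_Xy):
    from sklearn.model_selection import StratifiedKFold

    X, y = stage_Xy
    codes = np.array([STAGES.index(v) for v in y])
    skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
    global_frac = np.bincount(codes, minlength=6) / len(codes)
    for _, te in skf.split(X, codes):
        fold_counts = np.bincount(codes[te], minlength=6)
        expect = global_frac * len(te)
        assert np.all(np.abs(fold_counts - expect) <= 1.0)
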