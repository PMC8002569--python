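import numpy as np
import pytest

import somnowave as sw
from somnowave.ensemble import make_bagging, predict_labels, predict_scores
from somnowave.stages import STAGES


class TestFitTree:
    def test_separable_midpoint_split(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = ["W", "W", "S1", "S1"]
        tree = sw.fit_tree(X, y, max_splits=1)
        assert tree.tree_.threshold[0] == pytest.approx(2.5)
        assert list(predict_labels(tree, X)) == y

    def test_single_class_needs_no_split(self):
        tree = sw.fit_tree(np.arange(5.0), ["S2"] * 5)
        assert list(predict_labels(tree, np.array([0.0, 10.0]))) == ["S2", "S2"]

    def test_zero_splits_gives_majority_stump(self):
        X = np.arange(6.0)
        y = ["W", "W", "W", "S1", "S1", "REM"]
        stump = sw.fit_tree(X, y, max_splits=0)
        assert list(predict_labels(stump, X)) == ["W"] * 6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sw.fit_tree(np.empty((0, 2)), [])


class TestFitBagged:
    def test_single_full_tree_fits_training_set(self, rng):
        X = rng.standard_normal((30, 3))
        y = [STAGES[i % 6] for i in range(30)]
        # bootstrap may drop points, so allow a forest to memorize instead
        model = sw.fit_bagged(X, y, n_learners=100, seed=0)
        labels, _ = model.predict(X)
        assert np.mean(labels == np.array(y)) > 0.9

    def test_deterministic_given_seed(self, stage_Xy):
        X, y = stage_Xy
        a = sw.fit_bagged(X, y, n_learners=10, seed=3)
        b = sw.fit_bagged(X, y, n_learners=10, seed=3)
        pa, _ = a.predict(X)
        pb, _ = b.predict(X)
        assert np.array_equal(pa, pb)

    def test_scores_are_distributions(self, stage_Xy):
        X, y = stage_Xy
        model = sw.fit_bagged(X[:120], y[:120], n_learners=5, seed=0)
        _, scores = model.predict(X[:20])
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-12)
        assert scores.shape == (20, 6)

    def test_out_of_bag_beats_chance(self, stage_Xy):
        X, y = stage_Xy
        est = make_bagging(30, None, seed=1).set_params(oob_score=True)
        from somnowave.ensemble import _encode

        est.fit(X, _encode(y))
        assert 1.0 - est.oob_score_ < 5.0 / 6.0

    def test_bagging_not_worse_than_worst_member_on_training_data(self, stage_Xy):
        X, y = stage_Xy
        model = sw.fit_bagged(X, y, n_learners=15, max_splits=8, seed=2)
        labels, _ = model.predict(X)
        y_arr = np.array(y)
        ens_err = np.mean(labels != y_arr)
        member_errs = [
            np.mean(predict_labels(t, X) != y_arr) for t in model.trees
        ]
        assert ens_err <= max(member_errs) + 1e-12

    def test_learning_rate_accepted_and_inert(self, stage_Xy, caplog):
        X, y = stage_Xy
        import logging

        with caplog.at_level(logging.INFO, logger="somnowave.ensemble"):
            a = sw.fit_bagged(X[:60], y[:60], n_learners=3, seed=0, learning_rate=1.0)
        assert "ignored" in caplog.text
        b = sw.fit_bagged(X[:60], y[:60], n_learners=3, seed=0)
        pa, _ = a.predict(X[:30])
        pb, _ = b.predict(X[:30])
        assert np.array_equal(pa, pb)


class TestTune:
    def test_single_point_grid(self, stage_Xy):
        X, y = stage_Xy
        surface, best = sw.tune(X, y, [5], [None], k=3, seed=0)
        assert surface.shape == (1, 1)
        assert 0.0 <= surface[0, 0] <= 1.0
        assert best == (5, None)

    def test_separable_synthetic_data_scores_near_zero_error(self, stage_Xy):
        X, y = stage_Xy
        surface, best = sw.tune(X, y, [10, 40], [None], k=5, seed=1)
        assert surface.min() < 0.05
        assert best[0] in (10, 40)

    def test_error_curve_improves_with_more_trees_on_average(self, stage_Xy):
        """More learners should not hurt CV error in expectation."""
        X, y = stage_Xy
        lo, hi = [], []
        for seed in range(5):
            surface, _ = sw.tune(X, y, [2, 40], [8], k=4, seed=seed)
            lo.append(surface[0, 0])
            hi.append(surface[1, 0])
        assert np.mean(hi) <= np.mean(lo) + 1e-12

    def test_empty_grid_rejected(self, stage_Xy):
        X, y = stage_Xy
        with pytest.raises(ValueError):
            sw.tune(X, y, [], [None], k=3)


def test_scores_tie_breaks_to_earliest_stage():
    scores = np.array([[0.25, 0.25, 0.25, 0.25, 0.0, 0.0]])
    from somnowave.ensemble import _decode

    assert _decode(np.argmax(scores, axis=1))[0] == "W"
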