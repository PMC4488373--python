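"""Replicate forests: OOB statistics, importance, averaged predictions."""

import numpy as np
import pandas as pd
import pytest

from streamsdm.ensemble import (EnsemblePrediction, ModelConfig, bootstrap_oob_fraction,
                                cv_map, fit_ensemble, fit_replicate, importance_summary,
                                predict_ensemble)
from streamsdm.labels import TrainingSet


def _training(labels):
    rows = pd.DataFrame({
        "unit_id": np.arange(len(labels)),
        "label": labels,
        "label_source": ["presence" if v else "pseudoabsence" for v in labels],
    })
    return TrainingSet(1, rows)


def _scores(X, cols=None):
    cols = cols or [f"PC{j + 1}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    df.index.name = "unit_id"
    return df


def _signal_data(rng, n=400, p=5):
    """Balanced labels determined by the sign of the first column."""
    X = rng.normal(size=(n, p))
    order = np.argsort(X[:, 0])
    X = X[np.concatenate([order[:n // 2], order[n // 2:]])]
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return _scores(X), _training(y)


class TestFitReplicate:
    def test_candidate_variables_per_split_floor_sqrt(self, rng):
        scores, training = _signal_data(rng, n=60, p=7)
        model = fit_replicate(training, scores, ModelConfig(n_trees=11), 0,
                              compute_importance=False)
        assert model.forest.estimators_[0].max_features_ == 2  # floor(sqrt(7))

    def test_separable_signal_has_low_oob_error(self, rng):
        scores, training = _signal_data(rng, n=400, p=5)
        model = fit_replicate(training, scores, ModelConfig(n_trees=201), 3,
                              compute_importance=False)
        assert model.oob_error < 0.05

    def test_label_noise_gives_chance_oob_error(self):
        """With permuted labels OOB error hovers around 50%."""
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 4))
            y = rng.permutation([0] * 100 + [1] * 100)
            m = fit_replicate(_training(y), _scores(X), ModelConfig(n_trees=101), seed,
                              compute_importance=False)
            errs.append(m.oob_error)
        assert np.mean(errs) == pytest.approx(0.5, abs=0.07)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        ts = TrainingSet.__new__(TrainingSet)  # bypass the balance invariant
        ts.replicate_id = 1
        ts.rows = pd.DataFrame({"unit_id": np.arange(20), "label": np.ones(20, dtype=int),
                                "label_source": ["presence"] * 20})
        with pytest.raises(ValueError, match="both classes"):
            fit_replicate(ts, _scores(X), ModelConfig(n_trees=11), 0)

    def test_oob_fraction_of_forest_matches_bootstrap_limit(self, rng):
        """Mean share of rows out-of-bag per tree ~ (1-1/n)^n ~ 36.8%."""
        scores, training = _signal_data(rng, n=500, p=4)
        model = fit_replicate(training, scores, ModelConfig(n_trees=201), 1,
                              compute_importance=False)
        fracs = [1 - np.unique(s).size / 500 for s in model.forest.estimators_samples_]
        assert np.mean(fracs) == pytest.approx(1 / np.e, abs=0.01)


class TestPredictEnsemble:
    def test_single_replicate_average_is_identity(self, rng):
        scores, training = _signal_data(rng, n=100, p=3)
        model = fit_replicate(training, scores, ModelConfig(n_trees=51), 0,
                              compute_importance=False)
        pred = predict_ensemble([model], scores)
        np.testing.assert_array_equal(pred.mean.to_numpy(),
                                      pred.matrix["rep1"].to_numpy())
        assert (pred.mean >= 0).all() and (pred.mean <= 1).all()

    def test_mean_is_arithmetic_mean_of_replicates(self, rng):
        scores, training = _signal_data(rng, n=100, p=3)
        cfg = ModelConfig(n_trees=51, n_replicates=2, seed=9)
        models = fit_ensemble([TrainingSet(1, training.rows), TrainingSet(2, training.rows)],
                              scores, cfg, compute_importance=False)
        pred = predict_ensemble(models, scores)
        np.testing.assert_allclose(pred.mean, pred.matrix.mean(axis=1), atol=1e-12)

    def test_column_mismatch_rejected(self, rng):
        scores, training = _signal_data(rng, n=60, p=3)
        model = fit_replicate(training, scores, ModelConfig(n_trees=11), 0,
                              compute_importance=False)
        other = scores.rename(columns={"PC1": "PCx"})
        with pytest.raises(ValueError, match="columns"):
            predict_ensemble([model], other)

    def test_deterministic_under_fixed_seed(self, rng):
        scores, training = _signal_data(rng, n=120, p=4)
        cfg = ModelConfig(n_trees=51, n_replicates=2, seed=5)
        sets = [TrainingSet(1, training.rows), TrainingSet(2, training.rows)]
        a = predict_ensemble(fit_ensemble(sets, scores, cfg, False), scores)
        b = predict_ensemble(fit_ensemble(sets, scores, cfg, False), scores)
        np.testing.assert_array_equal(a.mean.to_numpy(), b.mean.to_numpy())


class TestImportance:
    def test_signal_variable_ranks_first_in_most_runs(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores, training = _signal_data(rng, n=150, p=5)
            m = fit_replicate(training, scores, ModelConfig(n_trees=201), seed)
            if m.importance.idxmax() == "PC1":
                wins += 1
        assert wins >= 18

    def test_noise_variable_importance_near_zero(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            scores, training = _signal_data(rng, n=150, p=5)
            m = fit_replicate(training, scores, ModelConfig(n_trees=201), seed)
            vals.append(m.importance["PC5"])  # independent of the labels
        assert abs(np.mean(vals)) < 0.02

    def test_summary_invariant_to_replicate_order(self, rng):
        scores, training = _signal_data(rng, n=100, p=4)
        cfg = ModelConfig(n_trees=51, n_replicates=2, seed=2)
        models = fit_ensemble([TrainingSet(1, training.rows), TrainingSet(2, training.rows)],
                              scores, cfg)
        a = importance_summary(models)
        b = importance_summary(models[::-1])
        pd.testing.assert_frame_equal(a, b)


class TestCvMap:
    def _pred(self, matrix):
        m = pd.DataFrame(matrix, columns=[f"rep{i + 1}" for i in range(matrix.shape[1])])
        mean = m.mean(axis=1)
        sd = m.std(axis=1, ddof=1)
        cv = (sd / mean.replace(0, np.nan)).fillna(0.0)
        return EnsemblePrediction(mean, m, cv)

    def test_identical_replicates_zero_cv(self):
        pred = self._pred(np.tile([[0.3], [0.7]], (1, 4)))
        assert (cv_map(pred) == 0).all()

    def test_hand_computed_cv(self):
        pred = self._pred(np.array([[0.4, 0.6]]))
        # sd = 0.1414..., mean = 0.5
        assert cv_map(pred).iloc[0] == pytest.approx(np.sqrt(0.02) / 0.5)

    def test_cv_nonnegative_and_needs_replicates(self, rng):
        pred = self._pred(rng.random((10, 3)))
        assert (cv_map(pred) >= 0).all()
        with pytest.raises(ValueError):
            cv_map(self._pred(rng.random((5, 1))))


def test_bootstrap_exclusion_fraction_near_one_over_e():
    got = bootstrap_oob_fraction(2000, 200, seed=1)
    assert got == pytest.approx(1 / np.e, abs=0.003)
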