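"""Imputer backends: logistic, KNN (vs brute-force oracle), random forest,
multiple imputation, and propensity harmonization."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit as logit_fn

from crossimpute import (ImputerConfig, SyntheticConfig, fit_imputer, fit_knn,
                         fit_propensity, fit_rf, fit_single_logit,
                         generate_donor_target, predict_status, run_mi)
from crossimpute.imputers import _knn_vote_share
from crossimpute.logical import (DOC_LOGICAL, IMPUTED_DOC, IMPUTED_UNDOC,
                                 POSSIBLY_UNDOC, STATUS_COL, TRUE_UNDOC,
                                 TRUTH_COL)
from conftest import labeled_pool_table


def knn_oracle(X_train, y_train, X_query, k):
    """Exhaustive all-pairs-distance nearest-neighbour vote, including every
    neighbour tied with the k-th distance; vote share returned."""
    out = []
    for q in X_query:
        d = np.sqrt(((X_train - q) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")
        kth = d[order[k - 1]]
        included = d <= kth * (1 + 1e-12) + 1e-300
        out.append(y_train[included].mean())
    return np.array(out)


class TestSingleLogit:
    def test_separable_toy_probabilities_are_extreme(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        y = np.array([0, 0, 0, 1, 1, 1])
        t = labeled_pool_table(X, y)
        fitted = fit_single_logit(t, ImputerConfig(method="logit"))
        p = fitted.predict_proba(t)
        assert (p[:3] < 0.01).all() and (p[3:] > 0.99).all()

    def test_balanced_null_predictor_gives_flat_probabilities(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]] * 10)
        y = np.array([0, 1, 0, 1] * 10)
        t = labeled_pool_table(X, y)
        fitted = fit_single_logit(t, ImputerConfig(method="logit"))
        p = fitted.predict_proba(t)
        assert np.allclose(p, 0.5, atol=0.01)

    def test_intercept_only_model_is_training_prevalence(self):
        # closed form: constant probability expit(logit(0.3)) = 0.3
        X = np.empty((10, 0))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        t = labeled_pool_table(X, y)
        fitted = fit_single_logit(t, ImputerConfig(method="logit"))
        p = fitted.predict_proba(t)
        assert np.allclose(p, expit(logit_fn(0.3)))
        assert np.allclose(p, 0.3)

    def test_training_on_non_pool_rows_rejected(self, small_donor):
        with pytest.raises(ValueError, match="possibly-undocumented"):
            fit_single_logit(small_donor, ImputerConfig(method="logit"))


class TestPredictStatus:
    def _constant_model(self, prob):
        X = np.empty((6, 0))
        y = np.array([1, 1, 0, 0, 0, 0])
        t = labeled_pool_table(X, y)
        fitted = fit_single_logit(t, ImputerConfig(method="logit"))
        fitted.constant_prob = prob
        return fitted, t

    def test_probability_just_above_threshold_is_undocumented(self):
        fitted, t = self._constant_model(0.51)
        out = predict_status(fitted, t)
        assert (out.data[STATUS_COL] == IMPUTED_UNDOC).all()

    def test_probability_exactly_at_threshold_is_documented(self):
        # the cutoff is a strict inequality
        fitted, t = self._constant_model(0.50)
        out = predict_status(fitted, t)
        assert (out.data[STATUS_COL] == IMPUTED_DOC).all()

    def test_logically_documented_rows_never_reimputed(self):
        fitted, t = self._constant_model(0.9)
        df = t.data.copy()
        df.loc[0, STATUS_COL] = DOC_LOGICAL
        bad = t.with_data(df)
        with pytest.raises(ValueError, match="never re-imputed"):
            predict_status(fitted, bad)

    def test_manifest_mismatch_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = (X[:, 0] > 0).astype(int)
        t = labeled_pool_table(X, y)
        fitted = fit_single_logit(t, ImputerConfig(method="logit"))
        broken = t.with_data(t.data.drop(columns=["x1"]),
                             schema=[v for v in t.schema if v.name != "x1"])
        with pytest.raises(ValueError, match="manifest"):
            predict_status(fitted, broken)

    @pytest.mark.parametrize("method", ["logit", "knn", "rf"])
    def test_labels_agree_with_thresholded_scores(self, method, small_pool):
        # no internal inconsistency between scores and classifications
        cfg = ImputerConfig(method=method, k_grid=(15,), n_trees=50, seed=3)
        fitted = fit_imputer(small_pool, cfg)
        out = predict_status(fitted, small_pool, cfg)
        expected = np.where(out.data["status_score"] > cfg.threshold,
                            IMPUTED_UNDOC, IMPUTED_DOC)
        assert (out.data[STATUS_COL] == expected).all()


class TestKNN:
    def test_query_equal_to_training_point_with_k1(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0],
                      [0.5, 0.8]])
        y = np.array([1, 0, 1, 0, 1])
        t = labeled_pool_table(X, y)
        fitted = fit_knn(t, ImputerConfig(method="knn", k_grid=(1,)))
        p = fitted.predict_proba(t)
        assert np.array_equal(p, y.astype(float))

    def test_unanimous_training_labels(self):
        X = np.random.default_rng(1).normal(size=(12, 3))
        t = labeled_pool_table(X, np.ones(12, int))
        for k in (1, 3, 7):
            fitted = fit_knn(t, ImputerConfig(method="knn", k_grid=(k,)))
            assert (fitted.predict_proba(t) == 1.0).all()

    def test_majority_vote_matches_exhaustive_sort_on_five_points(self):
        X = np.array([[0.0], [0.1], [0.2], [0.9], [1.0]])
        y = np.array([1, 1, 0, 0, 0])
        t = labeled_pool_table(X, y)
        fitted = fit_knn(t, ImputerConfig(method="knn", k_grid=(3,)))
        enc = fitted.encoder
        got = fitted.predict_proba(t)
        want = knn_oracle(enc.transform(t), y.astype(float),
                          enc.transform(t), 3)
        assert np.allclose(got, want)

    def test_distance_ties_at_kth_neighbour_all_included(self):
        # four equidistant neighbours, k=2: all four must vote
        X_train = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        y = np.array([1.0, 1.0, 1.0, 0.0])
        share = _knn_vote_share(X_train, y, np.array([[0.0, 0.0]]), k=2)
        assert share[0] == pytest.approx(0.75)

    def test_k_exceeding_training_size_rejected(self):
        t = labeled_pool_table(np.zeros((4, 1)), np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError, match="exceeds"):
            fit_knn(t, ImputerConfig(method="knn", k_grid=(5,)))

    def test_matches_brute_force_oracle_on_small_tables(self, small_pool):
        train = small_pool.subset(np.arange(len(small_pool.data)) < 40)
        query = small_pool.subset(
            (np.arange(len(small_pool.data)) >= 40)
            & (np.arange(len(small_pool.data)) < 55))
        y = (train.data[TRUTH_COL] == TRUE_UNDOC).to_numpy(float)
        for k in (1, 3, 5, 17, 31):
            fitted = fit_knn(train, ImputerConfig(method="knn", k_grid=(k,)))
            got = fitted.predict_proba(query)
            want = knn_oracle(fitted.encoder.transform(train), y,
                              fitted.encoder.transform(query), k)
            assert np.allclose(got, want), f"k={k}"

    def test_cv_tuning_selects_from_grid(self, small_pool):
        cfg = ImputerConfig(method="knn", k_grid=(5, 15), cv_folds=4,
                            cv_repeats=1, seed=0)
        fitted = fit_knn(small_pool, cfg)
        assert fitted.tuning_trace["selected_k"] in (5, 15)
        assert set(fitted.tuning_trace["cv_scores"]) == {5, 15}


class TestRandomForest:
    def test_single_class_training_data(self):
        X = np.random.default_rng(2).normal(size=(30, 2))
        t = labeled_pool_table(X, np.zeros(30, int))
        fitted = fit_rf(t, ImputerConfig(method="rf", n_trees=20))
        assert (fitted.predict_proba(t) == 0.0).all()

    def test_separated_gaussian_clusters_recovered(self):
        # Bayes error is essentially zero: held-out accuracy must be >= 0.99
        rng = np.random.default_rng(7)
        n = 2000
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 2)) + 8.0 * y[:, None]
        t = labeled_pool_table(X, y)
        tr = np.arange(n) < 1500
        fitted = fit_rf(t.subset(tr), ImputerConfig(method="rf", n_trees=500,
                                                    seed=1))
        pred = fitted.predict_proba(t.subset(~tr)) > 0.5
        assert (pred == y[~tr].astype(bool)).mean() >= 0.99

    def test_same_seed_identical_votes(self, small_pool):
        cfg = ImputerConfig(method="rf", n_trees=60, seed=11)
        p1 = fit_rf(small_pool, cfg).predict_proba(small_pool)
        p2 = fit_rf(small_pool, cfg).predict_proba(small_pool)
        assert np.array_equal(p1, p2)

    def test_mtry_exceeding_predictors_rejected(self):
        t = labeled_pool_table(np.zeros((10, 2)),
                               np.array([0, 1] * 5))
        with pytest.raises(ValueError, match="mtry"):
            fit_rf(t, ImputerConfig(method="rf", mtry_grid=(5,)))


class TestMultipleImputation:
    def _train_target(self, small_pool):
        n = len(small_pool.data)
        train = small_pool.subset(np.arange(n) < n * 3 // 4)
        target = small_pool.subset(np.arange(n) >= n * 3 // 4)
        return train, target

    def test_completed_vectors_share_target_ids(self, small_pool):
        train, target = self._train_target(small_pool)
        cfg = ImputerConfig(method="mi_logit", m_imputations=4, seed=5)
        mi = run_mi(train, target, cfg)
        assert mi.m == 4
        assert list(mi.completed.index) == list(target.ids)

    def test_m1_reduces_to_single_stochastic_imputation(self, small_pool):
        train, target = self._train_target(small_pool)
        cfg = ImputerConfig(method="mi_logit", m_imputations=1, seed=5)
        mi = run_mi(train, target, cfg)
        assert mi.completed.shape == (len(target.data), 1)
        assert set(np.unique(mi.completed)) <= {0, 1}

    def test_same_seed_identical_draws(self, small_pool):
        train, target = self._train_target(small_pool)
        cfg = ImputerConfig(method="mi_logit", m_imputations=3, seed=5)
        a = run_mi(train, target, cfg).completed
        b = run_mi(train, target, cfg).completed
        pd.testing.assert_frame_equal(a, b)

    def test_outcomes_enter_imputation_model_only_when_asked(self, small_pool):
        train, target = self._train_target(small_pool)
        cfg = ImputerConfig(method="mi_logit", m_imputations=2, seed=5)
        with_out = run_mi(train, target, cfg, include_outcomes=True)
        without = run_mi(train, target, cfg, include_outcomes=False)
        assert with_out.tuning_trace["outcomes_in_model"]
        assert not without.tuning_trace["outcomes_in_model"]


class TestPropensity:
    def test_identical_sampling_discriminates_at_chance(self):
        cfg = SyntheticConfig(n_donor=6000, n_target=6000, seed=17,
                              sampling_differential={})
        donor, target = generate_donor_target(cfg)
        d2, t2 = fit_propensity(donor, target)
        scores = np.concatenate([d2.data["propensity_score"],
                                 t2.data["propensity_score"]])
        member = np.concatenate([np.ones(len(d2.data)),
                                 np.zeros(len(t2.data))])
        # in-sample AUC; chance plus a small overfit allowance
        order = np.argsort(scores)
        ranks = np.empty(len(scores))
        ranks[order] = np.arange(1, len(scores) + 1)
        n1, n0 = member.sum(), (1 - member).sum()
        auc = (ranks[member == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert abs(auc - 0.5) < 0.035

    def test_constructed_differential_sign_recovered(self):
        cfg = SyntheticConfig(
            n_donor=6000, n_target=6000, seed=18,
            sampling_differential={"english_difficulty": 1.5})
        donor, target = generate_donor_target(cfg)
        d2, t2 = fit_propensity(donor, target)
        stacked = pd.concat([d2.data, t2.data])
        eng = stacked["english_difficulty"].fillna(0)
        # target oversamples the level, so donor-membership propensity is
        # lower where the level is present
        assert (stacked.loc[eng == 1, "propensity_score"].mean()
                < stacked.loc[eng == 0, "propensity_score"].mean())

    def test_predictor_manifest_grows_by_exactly_one(self):
        cfg = SyntheticConfig(n_donor=500, n_target=500, seed=19)
        donor, target = generate_donor_target(cfg)
        before = len(donor.names_with_role("predictor"))
        d2, t2 = fit_propensity(donor, target)
        assert len(d2.names_with_role("predictor")) == before + 1
        assert len(t2.names_with_role("predictor")) == before + 1
        assert "propensity_score" in d2.data.columns
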