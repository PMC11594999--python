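import numpy as np
import pandas as pd
import pytest
from scipy.linalg import eigh
from scipy.stats import norm

from flimtex.discriminant import (
    aggregate_per_patient,
    f_score,
    fit_lda,
    holdout_validate,
    loo_validate,
    stepwise_select,
)


def _two_gaussians(rng, n, d=2, delta=2.0):
    X = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(0, 1, (n, d))])
    X[n:, 0] += delta
    y = np.repeat([0, 1], n)
    return X, y


class TestFitLDA:
    def test_direction_matches_closed_form_and_eigenproblem(self, rng):
        X, y = _two_gaussians(rng, 300, d=4)
        X[:, 1] = 0.5 * X[:, 0] + rng.normal(0, 1, 600)  # correlated features
        m = fit_lda(X, y)
        delta = m.class_means[1] - m.class_means[0]
        w_cf = np.linalg.solve(m.S_W, delta)
        w_cf /= np.linalg.norm(w_cf)
        assert abs(m.w @ w_cf) > 1 - 1e-10
        # generalized eigenproblem S_B w = lambda S_W w, top eigenvector
        _, vecs = eigh(m.S_B, m.S_W)
        w_eig = vecs[:, -1] / np.linalg.norm(vecs[:, -1])
        assert abs(m.w @ w_eig) > 1 - 1e-10

    def test_fisher_criterion_scale_invariant(self, rng):
        X, y = _two_gaussians(rng, 100)
        m = fit_lda(X, y)
        j = m.fisher_criterion()
        for c in (2.0, -3.5, 0.01):
            assert m.fisher_criterion(c * m.w) == pytest.approx(j)

    def test_identical_class_distributions_give_zero_criterion(self, rng):
        Xhalf = rng.normal(0, 1, (50, 2))
        X = np.vstack([Xhalf, Xhalf])
        y = np.repeat([0, 1], 50)
        m = fit_lda(X, y)
        assert m.fisher_criterion() == pytest.approx(0.0, abs=1e-20)

    def test_separable_1d_classes_classify_perfectly(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        m = fit_lda(X, y)
        assert (m.predict(X) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_lda(np.ones((4, 2)), np.zeros(4))

    def test_predictions_match_sklearn_lda(self, rng):
        # same pooled-covariance Gaussian rule, independent implementation
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        for _ in range(5):
            X = rng.normal(0, 1, (300, 4))
            X[:150] += rng.uniform(0.2, 1.0, 4)
            y = np.repeat([0, 1], 150)
            mine = fit_lda(X, y).predict(X)
            theirs = LinearDiscriminantAnalysis(solver="svd").fit(X, y).predict(X)
            assert (mine == theirs).all()

    def test_holdout_accuracy_near_bayes_rate(self, rng):
        # equal-covariance Gaussians, means 2 apart: Bayes rate Phi(1)
        X, y = _two_gaussians(rng, 10000, d=2, delta=2.0)
        rep = holdout_validate(X, y, seed=3, repeats=5)
        assert rep.accuracy == pytest.approx(norm.cdf(1.0), abs=0.02)


class TestStepwise:
    def test_informative_feature_beats_single_noise_feature(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(200 + s)
            X = rng.normal(0, 1, (200, 2))
            X[100:, 0] += 2.0
            y = np.repeat([0, 1], 100)
            sel, _ = stepwise_select(X, y, feature_names=["inf", "noise"])
            if "inf" in sel and "noise" not in sel:
                hits += 1
        assert hits >= 95

    def test_pure_noise_features_yield_empty_selection(self):
        rng = np.random.default_rng(42)
        X = rng.normal(0, 1, (120, 3))
        y = np.repeat([0, 1], 60)
        with pytest.warns(UserWarning, match="no feature"):
            sel, model = stepwise_select(X, y)
        assert sel == []
        assert model.selected_features == []

    def test_duplicated_informative_feature_selected_once(self, rng):
        X1 = rng.normal(0, 1, (200, 1))
        X1[100:] += 2.0
        X = np.hstack([X1, X1.copy()])
        y = np.repeat([0, 1], 100)
        sel, _ = stepwise_select(X, y, feature_names=["a", "a_copy"])
        assert len(sel) == 1

    def test_f_enter_must_exceed_f_remove(self, rng):
        with pytest.raises(ValueError):
            stepwise_select(rng.normal(0, 1, (20, 2)), np.repeat([0, 1], 10), 2.0, 3.0)


class TestValidation:
    def test_loo_perfect_on_separable_data(self):
        X = np.concatenate([np.arange(5.0), np.arange(5.0) + 50])[:, None]
        y = np.repeat([0, 1], 5)
        rep = loo_validate(X, y)
        assert rep.accuracy_loo == 1.0

    def test_loo_not_optimistic_versus_resubstitution(self):
        worse = 0
        for s in range(50):
            rng = np.random.default_rng(900 + s)
            X = rng.normal(0, 1, (40, 3))
            X[20:, 0] += 1.0
            y = np.repeat([0, 1], 20)
            rep = loo_validate(X, y)
            if rep.accuracy_loo <= rep.accuracy + 1e-12:
                worse += 1
        assert worse >= 45  # LOO accuracy <= resubstitution in >= 90% of runs

    def test_permuted_labels_give_chance_level_loo(self, rng):
        X = rng.normal(0, 1, (200, 2))
        X[100:, 0] += 2.0
        y = rng.permutation(np.repeat([0, 1], 100))
        rep = loo_validate(X, y)
        # binomial noise around 0.5 at n=200: 4 sigma ~ 0.14
        assert abs(rep.accuracy_loo - 0.5) < 0.15

    def test_patient_level_loo_groups_units(self, rng):
        X = rng.normal(0, 1, (30, 2))
        X[15:, 0] += 5.0
        y = np.repeat([0, 1], 15)
        units = np.repeat(np.arange(10), 3)
        rep = loo_validate(X, y, unit_ids=units)
        assert rep.accuracy_loo >= 0.9

    def test_holdout_deterministic_for_fixed_seed(self, rng):
        X, y = rng.normal(0, 1, (80, 2)), np.repeat([0, 1], 40)
        X[40:, 0] += 1.5
        r1 = holdout_validate(X, y, seed=11)
        r2 = holdout_validate(X, y, seed=11)
        assert r1.per_repeat_accuracy == r2.per_repeat_accuracy
        assert r1.f_score_mean == r2.f_score_mean

    def test_holdout_separable_f_score_one(self):
        X = np.concatenate([np.arange(20.0), np.arange(20.0) + 100])[:, None]
        y = np.repeat([0, 1], 20)
        rep = holdout_validate(X, y, seed=1)
        assert rep.f_score_mean == 1.0
        assert rep.f_score_sd == 0.0

    def test_holdout_accuracy_near_bayes_for_d1(self, rng):
        X = np.vstack([rng.normal(0, 1, (2000, 2)), rng.normal(0, 1, (2000, 2))])
        X[2000:, 0] += 1.0
        y = np.repeat([0, 1], 2000)
        rep = holdout_validate(X, y, seed=5)
        assert rep.accuracy == pytest.approx(norm.cdf(0.5), abs=0.03)


class TestFScore:
    def test_perfect_confusion(self):
        assert f_score([[50, 0], [0, 50]]) == 1.0

    def test_uniform_confusion_is_half(self):
        assert f_score([[25, 25], [25, 25]]) == 0.5

    def test_symmetric_confusion_macro_equals_per_class(self):
        cm = [[30, 10], [10, 30]]
        per = f_score(cm, averaging="per_class")
        assert per[0] == per[1] == f_score(cm, averaging="macro")

    def test_zero_predicted_positives_flagged_as_zero(self):
        assert f_score([[10, 0], [5, 0]], averaging="per_class")[1] == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            f_score([[1, -1], [0, 2]])


class TestAggregation:
    def test_patient_mean_of_two_cells(self):
        df = pd.DataFrame(
            {"patient_id": ["p1", "p1"], "group": ["scd", "scd"], "lbp_mean": [10.0, 12.0]}
        )
        out = aggregate_per_patient(df)
        assert out.loc[0, "lbp_mean"] == 11.0
        assert out.loc[0, "n_cells"] == 2

    def test_single_cell_patient_is_identity(self):
        df = pd.DataFrame({"patient_id": ["p1"], "group": ["scd"], "x": [3.7]})
        assert aggregate_per_patient(df).loc[0, "x"] == 3.7

    def test_cell_order_invariance(self, rng):
        df = pd.DataFrame(
            {
                "patient_id": rng.permutation(np.repeat(["a", "b", "c"], 4)),
                "x": rng.normal(size=12),
            }
        )
        shuffled = df.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(
            aggregate_per_patient(df), aggregate_per_patient(shuffled)
        )

    def test_inconsistent_group_within_patient_rejected(self):
        df = pd.DataFrame({"patient_id": ["p", "p"], "group": ["scd", "control"], "x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="not constant"):
            aggregate_per_patient(df)
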