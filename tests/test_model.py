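"""Preprocessing, the LASSO-logistic path, metrics, nested CV accounting,
selection frequency and the PCA variant."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

import lvshape as lv
from lvshape.model import _lambda_grid


def make_table(X, y):
    cols = [f"f{i}" for i in range(X.shape[1])]
    return lv.FeatureTable(X=pd.DataFrame(X, columns=cols), y=y)


class TestQuantileTransform:
    def test_empirical_cdf_on_train(self):
        train = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        tr, _ = lv.quantile_transform(train, train)
        np.testing.assert_allclose(tr.ravel(), [0, 0.25, 0.5, 0.75, 1.0])

    def test_test_values_clip_to_unit_interval(self):
        train = np.linspace(0, 1, 20).reshape(-1, 1)
        test = np.array([[-5.0], [5.0]])
        _, te = lv.quantile_transform(train, test)
        assert te[0, 0] == 0.0
        assert te[1, 0] == 1.0

    def test_rank_invariance_under_monotone_transforms(self):
        rng = np.random.default_rng(0)
        train = rng.normal(size=(50, 1))
        test = rng.normal(size=(20, 1))
        tr1, te1 = lv.quantile_transform(train, test)
        tr2, te2 = lv.quantile_transform(np.exp(train), np.exp(test))
        # train values are pure ranks -> identical
        np.testing.assert_allclose(tr1, tr2, atol=1e-12)
        # test values interpolate between train knots in the original
        # scale, so only their ordering is transform-invariant
        np.testing.assert_array_equal(np.argsort(te1.ravel()),
                                      np.argsort(te2.ravel()))
        np.testing.assert_allclose(te1, te2, atol=5e-3)


class TestLassoPath:
    def test_lambda_max_endpoint_is_null_model(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 12))
        y = (rng.random(80) < 0.6).astype(int)
        lams, B, b0s = lv.lasso_logistic_path(X, y)
        assert np.all(B[0] == 0.0)
        assert b0s[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())),
                                       abs=1e-9)

    def test_near_zero_penalty_matches_generic_optimizer(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        grid = _lambda_grid(lv.lambda_max(X, y), 40, 1e-6)
        _, B, b0s = lv.lasso_logistic_path(X, y, lambdas=grid)

        def nll(w):
            eta = np.clip(w[0] + X @ w[1:], -500, 500)
            return np.mean(np.log1p(np.exp(-(2 * y - 1) * eta)))

        res = minimize(nll, np.zeros(4), method="BFGS")
        np.testing.assert_allclose(B[-1], res.x[1:], atol=1e-3)
        assert b0s[-1] == pytest.approx(res.x[0], abs=1e-3)

    def test_duplicated_column_shares_weight(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 4))
        y = (rng.random(100) < 1 / (1 + np.exp(-X[:, 0] + 0.5 * X[:, 1]))
             ).astype(int)
        Xdup = np.c_[X, X[:, 0]]
        grid = _lambda_grid(lv.lambda_max(X, y), 30, 0.05)
        _, B1, _ = lv.lasso_logistic_path(X, y, lambdas=grid)
        _, B2, _ = lv.lasso_logistic_path(Xdup, y, lambdas=grid)
        combined = B2[:, 0] + B2[:, 4]
        np.testing.assert_allclose(combined, B1[:, 0], atol=1e-3)
        np.testing.assert_allclose(B2[:, 1:4], B1[:, 1:4], atol=1e-3)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            lv.lasso_logistic_path(X, np.ones(10))

    def test_sparsity_decreases_with_penalty(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 10))
        beta_true = np.r_[2.0, -1.5, 1.0, np.zeros(7)]
        y = (rng.random(120) < 1 / (1 + np.exp(-X @ beta_true))).astype(int)
        _, B, _ = lv.lasso_logistic_path(X, y)
        nnz = (np.abs(B) > 1e-8).sum(axis=1)
        # non-decreasing along the decreasing-lambda path, allowing rare
        # coordinate-descent ties
        drops = np.diff(nnz.astype(int))
        assert (drops < -1).sum() == 0
        assert (drops < 0).mean() < 0.05
        assert nnz[0] == 0 and nnz[-1] >= 3


class TestMetrics:
    def test_confusion_arithmetic(self):
        y = np.r_[np.ones(95), np.zeros(75)].astype(int)
        scores = np.r_[np.ones(60), np.zeros(35), np.zeros(49), np.ones(26)]
        m = lv.metrics(y, scores)
        assert (m["tp"], m["fn"], m["tn"], m["fp"]) == (60, 35, 49, 26)
        assert m["sensitivity"] == pytest.approx(0.632, abs=5e-4)
        assert m["specificity"] == pytest.approx(0.653, abs=5e-4)
        assert m["balanced_accuracy"] == pytest.approx(0.642, abs=5e-4)

    def test_perfect_and_inverted_scores(self):
        y = np.array([0, 1, 0, 1, 1])
        assert lv.metrics(y, y.astype(float))["auc"] == 1.0
        assert lv.metrics(y, 1.0 - y)["auc"] == 0.0

    def test_six_subject_pair_count_oracle(self):
        y = np.array([0, 0, 1, 0, 1, 1])
        s = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9])
        pairs = [(i, j) for i in range(6) for j in range(6)
                 if y[i] == 1 and y[j] == 0]
        conc = np.mean([1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0
                        for i, j in pairs])
        assert lv.metrics(y, s)["auc"] == pytest.approx(conc, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_auc_matches_sklearn_with_ties(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        n = rng.integers(8, 40)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.random(n), 1)  # coarse grid forces ties
        assert lv.metrics(y, s)["auc"] == pytest.approx(
            roc_auc_score(y, s), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lv.metrics(np.ones(5), np.random.rand(5))


@pytest.fixture(scope="module")
def small_table():
    return lv.generate_feature_table(
        lv.TableSpec(n0=30, n1=30, effect_size=1.5, seed=5)
    )


@pytest.fixture(scope="module")
def small_cfg():
    return lv.ModelConfig(repeats=2, seed=11)


@pytest.fixture(scope="module")
def small_report(small_table, small_cfg):
    return lv.nested_cv(small_table, small_cfg)


class TestNestedCV:
    def test_evaluation_accounting(self, small_report):
        assert small_report.n_evaluations == 10
        assert set(small_report.folds["n_train"]) == {48}
        assert set(small_report.folds["n_test"]) == {12}

    def test_reproducible_under_seed(self, small_table, small_cfg, small_report):
        again = lv.nested_cv(small_table, small_cfg)
        pd.testing.assert_frame_equal(again.folds, small_report.folds)
        np.testing.assert_array_equal(again.coefs, small_report.coefs)

    def test_leakage_guard_training_side_unchanged(
        self, small_table, small_cfg, small_report
    ):
        """Replacing every outer-test block with a constant after fold
        assignment must not change any training-side quantity."""
        masked = lv.nested_cv(small_table, small_cfg, mask_test_features=123.0)
        np.testing.assert_array_equal(
            masked.folds["lambda"], small_report.folds["lambda"]
        )
        np.testing.assert_array_equal(masked.coefs, small_report.coefs)
        # while the test-side metrics do change
        assert not np.allclose(
            masked.folds["auc"], small_report.folds["auc"]
        )

    def test_signal_recovered(self, small_report):
        assert small_report.folds["auc"].mean() > 0.75

    def test_selection_frequency_ranking(self, small_report):
        sf = lv.selection_frequency(small_report)
        assert sf["frequency"].max() <= small_report.n_evaluations
        assert sf.iloc[0]["feature"] == "As"  # the informative column
        assert (sf["frequency"].to_numpy()[:-1]
                >= sf["frequency"].to_numpy()[1:]).all()

    def test_single_class_fold_impossible_by_stratification(self, small_report):
        # every evaluation computed metrics, which require both classes
        assert small_report.folds["auc"].notna().all()

    def test_global_preprocessing_mode_runs_and_differs(self, small_table):
        """The fit-once-on-everyone quantile alternative (sensitivity
        analysis) must run and generally select different penalties."""
        cfg = lv.ModelConfig(repeats=1, seed=11, preprocess_global=True)
        rep_g = lv.nested_cv(small_table, cfg)
        rep_f = lv.nested_cv(small_table, lv.ModelConfig(repeats=1, seed=11))
        assert rep_g.n_evaluations == rep_f.n_evaluations == 5
        assert not np.allclose(rep_g.coefs, rep_f.coefs)


class TestSelectionFrequency:
    def test_all_noise_at_lambda_max_selects_nothing(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 8))
        y = (rng.random(60) < 0.5).astype(int)
        lam = lv.lambda_max(X, y)
        _, B, _ = lv.lasso_logistic_path(X, y, lambdas=np.array([lam]))
        assert np.all(B == 0.0)

    def test_alphabetical_tie_break(self):
        rep = lv.CVReport(
            folds=pd.DataFrame({"auc": [0.5]}),
            coefs=np.array([[0.5, 0.0, 0.7]]),
            feature_names=["b", "a", "c"],
            config=lv.ModelConfig(),
            pooled_confusion={},
            response_correlation=pd.Series([0.1, 0.2, 0.3],
                                           index=["b", "a", "c"]),
        )
        sf = lv.selection_frequency(rep)
        assert list(sf["feature"]) == ["b", "c", "a"]


class TestPCAVariant:
    def test_three_latent_factors_give_three_components(self):
        rng = np.random.default_rng(0)
        n = 120
        Z = rng.normal(size=(n, 3))
        W = rng.normal(size=(3, 27)) * 2.0
        X = Z @ W + 0.3 * rng.normal(size=(n, 27))
        y = (rng.random(n) < 1 / (1 + np.exp(-Z[:, 0]))).astype(int)
        table = make_table(X, y)
        cfg = lv.ModelConfig(repeats=1, seed=0, variance_target=0.95)
        rep = lv.pca_pipeline(table, cfg)
        assert set(rep.folds["n_components"]) == {3}

    def test_full_variance_target_keeps_full_rank(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 10))
        y = (rng.random(60) < 0.5).astype(int)
        cfg = lv.ModelConfig(repeats=1, seed=0, variance_target=1.0)
        rep = lv.pca_pipeline(make_table(X, y), cfg)
        assert set(rep.folds["n_components"]) == {10}

    def test_single_feature_table_gives_one_component(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 1))
        y = (rng.random(60) < 0.5).astype(int)
        cfg = lv.ModelConfig(repeats=1, seed=0)
        rep = lv.pca_pipeline(make_table(X, y), cfg)
        assert set(rep.folds["n_components"]) == {1}


class TestSingleFeatureModel:
    def test_unknown_feature_rejected(self):
        table = lv.generate_feature_table(lv.TableSpec(n0=20, n1=20, seed=0))
        with pytest.raises(KeyError):
            lv.single_feature_model(table, "NotAFeature",
                                    lv.ModelConfig(repeats=1))

    def test_sole_informative_feature_matches_full_model(self):
        table = lv.generate_feature_table(
            lv.TableSpec(n0=120, n1=120, n_informative=1, effect_size=1.2,
                         rho=0.0, seed=3)
        )
        cfg = lv.ModelConfig(repeats=2, seed=4)
        full = lv.nested_cv(table, cfg).folds["auc"].mean()
        single = lv.single_feature_model(table, "As", cfg).folds["auc"].mean()
        assert single == pytest.approx(full, abs=0.03)

    def test_pure_noise_feature_is_chance_level(self):
        table = lv.generate_feature_table(
            lv.TableSpec(n0=100, n1=100, n_informative=0, seed=6)
        )
        cfg = lv.ModelConfig(repeats=3, seed=7)
        rep = lv.single_feature_model(table, "SA", cfg)
        assert rep.folds["auc"].mean() == pytest.approx(0.5, abs=0.1)


class TestFeatureTable:
    def test_missing_values_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]})
        with pytest.raises(ValueError, match="missing"):
            lv.FeatureTable(X=X, y=np.array([0, 1]))

    def test_nonbinary_response_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            lv.FeatureTable(X=X, y=np.array([0, 1, 2]))
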