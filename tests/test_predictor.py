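"""Feature ranking, OLS, inner model-size selection and nested LOOCV."""

import numpy as np
import pandas as pd
import pytest

from infradian.exceptions import InsufficientDataError, UndefinedCorrelationError
from infradian.predictor import (
    NestedLOOCV,
    PredictorConfig,
    fit_linear_model,
    inner_select_k,
    rank_features,
)

from conftest import MC_CONFIG
from oracles import oracle_fit_predict, oracle_inner_k, oracle_nested_loocv, oracle_rank


class TestRankFeatures:
    def test_signal_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 6))
        y = X[:, 3] + 1e-6 * rng.normal(size=20)
        assert rank_features(X, y)[0] == 3

    def test_tied_identical_columns_keep_input_order(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        X = np.column_stack([x, x, rng.normal(size=12)])
        y = x + rng.normal(size=12)
        order = list(rank_features(X, y))
        assert order.index(0) < order.index(1)

    def test_zero_variance_ranked_last(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.full(10, 3.0), rng.normal(size=(10, 2))])
        y = rng.normal(size=10)
        assert rank_features(X, y)[-1] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_sort(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        assert list(rank_features(X, y)) == oracle_rank(X, y)


class TestFitLinearModel:
    def test_two_points_exact_interpolation(self):
        lm = fit_linear_model(np.array([[0.0], [1.0]]), np.array([2.0, 5.0]))
        assert lm.predict(np.array([[0.0], [1.0], [0.5]])) == pytest.approx([2.0, 5.0, 3.5])

    def test_zero_features_predicts_mean(self):
        lm = fit_linear_model(np.empty((5, 0)), np.arange(5.0))
        assert lm.predict(np.empty((3, 0))) == pytest.approx([2.0, 2.0, 2.0])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        lm = fit_linear_model(X, y)
        xnew = rng.normal(size=3)
        expected = oracle_fit_predict(X, y, xnew)
        assert lm.predict(xnew[None, :])[0] == pytest.approx(expected, rel=1e-8)

    def test_collinear_duplicate_column_dropped_keeping_earlier(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        X = np.column_stack([x, x, rng.normal(size=15)])
        y = 2 * x + rng.normal(size=15)
        lm = fit_linear_model(X, y)
        assert list(lm.kept) == [0, 2]
        # prediction matches the reduced fit
        reduced = fit_linear_model(X[:, [0, 2]], y)
        xnew = rng.normal(size=3)
        assert lm.predict(xnew[None, :])[0] == pytest.approx(
            reduced.predict(xnew[[0, 2]][None, :])[0], rel=1e-10
        )

    def test_too_few_observations_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_linear_model(np.ones((2, 2)), np.arange(2.0))


class TestInnerSelectK:
    def test_noiseless_single_feature_selects_k1(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        y = 3.0 * X[:, 2]
        k, _ = inner_select_k(X, y, PredictorConfig(k_grid=(1, 2, 3)))
        assert k == 1

    def test_deterministic_on_noise(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        cfg = PredictorConfig(k_grid=(1, 2, 3, 4))
        assert inner_select_k(X, y, cfg) == inner_select_k(X, y, cfg)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        cfg = PredictorConfig(k_grid=(1, 2, 3))
        k, mses = inner_select_k(X, y, cfg)
        k_o, mses_o = oracle_inner_k(X, y, (1, 2, 3))
        assert k == k_o
        for kk in mses:
            assert mses[kk] == pytest.approx(mses_o[kk], rel=1e-10)


class TestNestedLOOCV:
    def test_noiseless_recovery_at_study_scale(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(35, 30))
        y = X[:, 1] - 2.0 * X[:, 7] + 0.5 * X[:, 20]
        res = NestedLOOCV(y, X).fit()  # default k grid, so the ranked prefix can cover all truth features
        assert res.pearson_r > 0.99
        for j in (1, 7, 20):
            assert res.feature_preference.iloc[j] == 1.0

    @pytest.mark.parametrize("seed,n,p", [(0, 8, 4), (1, 10, 6), (2, 7, 3)])
    def test_matches_brute_force_nested_oracle(self, seed, n, p):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        cfg = PredictorConfig(k_grid=(1, 2, 3))
        res = NestedLOOCV(y, X, config=cfg).fit()
        preds_o, ks_o, sels_o, r_o, p_o = oracle_nested_loocv(X, y, (1, 2, 3))
        assert res.fold_k == ks_o
        got_sels = [[res.model.feature_names.index(f) for f in fs] for fs in res.fold_features]
        assert got_sels == sels_o
        assert np.allclose(res.fittedvalues, preds_o, rtol=1e-10, atol=1e-12)
        assert res.pearson_r == pytest.approx(r_o, rel=1e-10)
        assert res.p_value == pytest.approx(p_o, rel=1e-10)

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        a = NestedLOOCV(y, X, config=MC_CONFIG).fit()
        b = NestedLOOCV(y, X, config=MC_CONFIG).fit()
        assert np.array_equal(a.fittedvalues, b.fittedvalues)
        assert a.pearson_r == b.pearson_r and a.fold_k == b.fold_k

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(14, 10))
        y = X[:, 0] + rng.normal(size=14)
        perm = rng.permutation(14)
        res = NestedLOOCV(y, X, config=MC_CONFIG).fit()
        res_p = NestedLOOCV(y[perm], X[perm], config=MC_CONFIG).fit()
        assert np.allclose(res_p.fittedvalues, res.fittedvalues[perm], rtol=1e-8)
        assert res_p.pearson_r == pytest.approx(res.pearson_r, rel=1e-8)
        assert np.allclose(res_p.feature_preference, res.feature_preference)

    def test_preference_bounds_and_total_selections(self, study_cohort):
        _, matrix, _, _, summaries = study_cohort
        from infradian.scan import predict_la24h

        res = predict_la24h(matrix, summaries, config=MC_CONFIG)
        pref = res.feature_preference
        assert ((pref >= 0) & (pref <= 1)).all()
        total = sum(len(f) for f in res.fold_features)
        assert pytest.approx(pref.sum() * res.nobs) == total
        assert res.nobs == 35 and len(pref) == 106

    def test_constant_target_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        with pytest.raises(UndefinedCorrelationError):
            NestedLOOCV(np.ones(8), X).fit()

    def test_too_few_mice_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InsufficientDataError):
            NestedLOOCV(rng.normal(size=5), rng.normal(size=(5, 3))).fit()

    def test_missing_values_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            NestedLOOCV(rng.normal(size=8), X)

    def test_from_dataframe_aligns_by_mouse_id(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"m{i}" for i in range(8)],
                         columns=["a", "b", "c"])
        y = pd.Series(rng.normal(size=8), index=list(reversed(X.index)))
        model = NestedLOOCV.from_dataframe(X, y)
        assert np.allclose(model.endog, y.loc[X.index].to_numpy())


class TestLeakageControl:
    def test_leaky_ranking_inflates_positive_significance(self):
        """The negative control: global (all-mice) feature ranking must show
        a clearly inflated positively-significant fraction on null cohorts,
        while the properly nested pipeline stays near the nominal level."""
        reps = 30
        proper = leaky = 0
        for s in range(reps):
            rng = np.random.default_rng(77_000 + s)
            X = rng.normal(size=(35, 106))
            y = rng.normal(size=35)
            model = NestedLOOCV(y, X, config=MC_CONFIG)
            res = model.fit()
            res_leak = model.fit(leak_feature_ranking=True)
            proper += res.p_value < 0.05 and res.pearson_r > 0
            leaky += res_leak.p_value < 0.05 and res_leak.pearson_r > 0
        assert leaky / reps > 0.15
        assert proper / reps < 0.15
        assert leaky > proper
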