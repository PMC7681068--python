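import numpy as np
import pandas as pd
import pytest

import plasmaclock as pc
from plasmaclock._solvers import cd_path, enet_path, make_lambda_path, ridge_path_svd
from conftest import kkt_violation


def _random_problem(seed, n=50, p=10):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, p))
    beta = rng.normal(size=p) * (rng.uniform(size=p) < 0.6)
    y = Z @ beta + rng.normal(size=n)
    return Z - Z.mean(0), y - y.mean()


class TestLogStandardize:
    def test_self_standardized_columns_are_unit(self, small_cohort):
        cohort, _ = small_cohort
        z, params = pc.log_standardize(cohort)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_external_params_give_constant_for_constant_column(self):
        intens = pd.DataFrame({"A": [100.0, 100.0, 100.0]}, index=["a", "b", "c"])
        cohort = pc.ProteomicCohort(
            intens,
            pd.DataFrame({"age": [1.0, 2, 3], "sex": 0, "group": "g"}, index=intens.index),
            pd.DataFrame({"protein_id": ["p"], "gene_symbol": ["g"]}, index=["A"]),
        )
        params = pc.StandardizationParams(
            means=pd.Series({"A": 3.0}), sds=pd.Series({"A": 0.5})
        )
        z, _ = pc.log_standardize(cohort, params=params)
        np.testing.assert_allclose(z["A"], (2.0 - 3.0) / 0.5)

    def test_training_params_reproduce_self_standardization(self, small_cohort):
        cohort, _ = small_cohort
        z1, params = pc.log_standardize(cohort)
        z2, _ = pc.log_standardize(cohort, params=params)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_zero_variance_analyte_dropped_with_warning(self):
        intens = pd.DataFrame(
            {"A": [1.0, 2.0, 3.0], "B": [5.0, 5.0, 5.0]}, index=["a", "b", "c"]
        )
        cohort = pc.ProteomicCohort(
            intens,
            pd.DataFrame({"age": [1.0, 2, 3], "sex": 0, "group": "g"}, index=intens.index),
            pd.DataFrame({"protein_id": ["p", "q"], "gene_symbol": ["g", "h"]},
                         index=["A", "B"]),
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            z, params = pc.log_standardize(cohort)
        assert list(z.columns) == ["A"]

    def test_missing_analyte_under_external_params_raises(self, small_cohort):
        cohort, _ = small_cohort
        params = pc.StandardizationParams(
            means=pd.Series({"missing": 0.0}), sds=pd.Series({"missing": 1.0})
        )
        with pytest.raises(KeyError):
            pc.log_standardize(cohort, params=params)


class TestSplit:
    def test_round_rule_at_cohort_scale(self):
        spec = pc.CohortSpec(n_subjects=3301, n_analytes=2, frac_informative=0.0, seed=0)
        cohort, _ = pc.generate_cohort(spec)
        split = pc.split_train_test(cohort, fraction=2 / 3, seed=0)
        assert len(split.train_ids) == 2201  # round(3301 * 2/3)
        assert len(split.test_ids) == 1100

    def test_same_seed_same_split_and_partition(self, small_cohort):
        cohort, _ = small_cohort
        s1 = pc.split_train_test(cohort, seed=4)
        s2 = pc.split_train_test(cohort, seed=4)
        assert s1.train_ids == s2.train_ids
        assert set(s1.train_ids) | set(s1.test_ids) == set(cohort.intensities.index)
        assert set(s1.train_ids) & set(s1.test_ids) == set()

    def test_bad_fraction_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError):
            pc.split_train_test(cohort, fraction=1.0)


class TestSolvers:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ridge_cd_matches_closed_form(self, seed):
        Zc, yc = _random_problem(seed)
        n, p = Zc.shape
        lams = np.array([1.0, 0.3, 0.05])
        coefs = cd_path(Zc, yc, 0.0, lams)
        for i, lam in enumerate(lams):
            closed = np.linalg.solve(Zc.T @ Zc / n + lam * np.eye(p), Zc.T @ yc / n)
            np.testing.assert_allclose(coefs[:, i], closed, atol=1e-6)

    def test_svd_route_equals_cd_route(self):
        Zc, yc = _random_problem(3)
        lams = make_lambda_path(Zc, yc, 0.0, 20)
        np.testing.assert_allclose(
            ridge_path_svd(Zc, yc, lams), cd_path(Zc, yc, 0.0, lams), atol=1e-6
        )

    def test_unpenalized_limit_recovers_ols(self):
        Zc, yc = _random_problem(4, n=80, p=5)
        coefs = cd_path(Zc, yc, 0.0, np.array([1e-10]))
        ols = np.linalg.lstsq(Zc, yc, rcond=None)[0]
        np.testing.assert_allclose(coefs[:, 0], ols, atol=1e-6)

    def test_lasso_null_solution_at_lambda_max(self):
        Zc, yc = _random_problem(5)
        n = Zc.shape[0]
        lam_max = np.abs(Zc.T @ yc).max() / n
        coefs = cd_path(Zc, yc, 1.0, np.array([lam_max * 1.0001, lam_max * 2]))
        assert (coefs == 0.0).all()

    def test_lasso_kkt_conditions_hold_along_path(self):
        Zc, yc = _random_problem(6)
        lams = make_lambda_path(Zc, yc, 1.0, 30)
        coefs = cd_path(Zc, yc, 1.0, lams)
        for i in range(0, 30, 5):
            assert kkt_violation(Zc, yc, coefs[:, i], lams[i], 1.0) < 1e-6

    @pytest.mark.parametrize("lam", [0.5, 0.1, 0.01])
    def test_lasso_agrees_with_reference_implementation(self, lam):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        Zc, yc = _random_problem(9, n=60, p=8)
        cd = cd_path(Zc, yc, 1.0, np.array([lam]))[:, 0]
        ref = sklearn_linear.Lasso(
            alpha=lam, fit_intercept=False, tol=1e-12, max_iter=200_000
        ).fit(Zc, yc).coef_
        np.testing.assert_allclose(cd, ref, atol=1e-5)

    def test_ridge_norm_shrinks_with_penalty(self):
        Zc, yc = _random_problem(7)
        lams = make_lambda_path(Zc, yc, 0.0, 40)
        coefs = ridge_path_svd(Zc, yc, lams)
        norms = np.linalg.norm(coefs, axis=0)
        assert (np.diff(norms) >= -1e-10).all()  # descending lambda -> growing norm

    def test_lasso_l1_norm_shrinks_with_penalty(self):
        Zc, yc = _random_problem(8)
        lams = make_lambda_path(Zc, yc, 1.0, 40)
        coefs = cd_path(Zc, yc, 1.0, lams)
        l1 = np.abs(coefs).sum(axis=0)
        assert (np.diff(l1) >= -1e-7).all()


class TestFitPenalizedClock:
    def test_train_mean_prediction_equals_mean_age(self, small_cohort):
        cohort, _ = small_cohort
        res = pc.build_clock(cohort, alpha=0.0, seed=2, n_lambda=30)
        z, _ = pc.log_standardize(
            pc.clock.apply_columns(cohort, res.model.feature_ids),
            params=res.model.standardization,
        )
        train = list(res.split.train_ids)
        preds = res.model.intercept + z.loc[train].to_numpy() @ res.model.weights.to_numpy()
        ages = cohort.ages.loc[train].to_numpy()
        assert preds.mean() == pytest.approx(ages.mean(), abs=1e-8)

    def test_selected_lambda_is_on_the_path(self, small_cohort):
        cohort, _ = small_cohort
        res = pc.build_clock(cohort, alpha=1.0, seed=2, n_lambda=30)
        assert res.model.lam in res.model.lambda_path

    def test_non_finite_input_rejected(self):
        Z = np.ones((20, 3))
        Z[0, 0] = np.nan
        with pytest.raises(ValueError):
            pc.fit_penalized_clock(Z, np.arange(20.0), alpha=0.0)

    def test_lasso_active_set_bounded_by_sample_size(self, small_cohort):
        cohort, _ = small_cohort
        res = pc.build_clock(cohort, alpha=1.0, seed=2, n_lambda=30)
        assert res.model.active_set_size <= min(
            len(res.split.train_ids), len(res.model.feature_ids)
        )


class TestPredictAndEvaluate:
    def test_zero_weights_predict_the_intercept(self, small_cohort):
        cohort, _ = small_cohort
        _, params = pc.log_standardize(cohort)
        model = pc.ClockModel(
            alpha=0.0, lam=1.0, lambda_path=np.array([1.0]), intercept=47.0,
            weights=pd.Series(0.0, index=params.analytes),
            standardization=params,
        )
        preds = pc.predict_age(model, cohort)
        np.testing.assert_allclose(preds.to_numpy(), 47.0)

    def test_prediction_invariant_to_column_order(self, small_cohort):
        cohort, _ = small_cohort
        res = pc.build_clock(cohort, alpha=0.0, seed=5, n_lambda=20)
        shuffled = pc.ProteomicCohort(
            cohort.intensities.iloc[:, ::-1],
            cohort.subject_meta,
            cohort.analyte_meta.iloc[::-1],
        )
        np.testing.assert_allclose(
            pc.predict_age(res.model, cohort).to_numpy(),
            pc.predict_age(res.model, shuffled).to_numpy(),
            atol=1e-10,
        )

    def test_missing_feature_error_mentions_subset_prediction(self, small_cohort):
        cohort, _ = small_cohort
        res = pc.build_clock(cohort, alpha=0.0, seed=5, n_lambda=20)
        masked = pc.apply_platform_mask(cohort, list(cohort.intensities.columns[:10]))
        with pytest.raises(KeyError, match="predict_with_subset"):
            pc.predict_age(res.model, masked)

    def test_perfect_and_antiperfect_predictions(self):
        chron = np.array([10.0, 20, 30, 40])
        ev = pc.evaluate_predictions(chron, chron)
        assert ev.r == pytest.approx(1.0) and ev.mae == 0.0
        ev2 = pc.evaluate_predictions(-chron + 50, chron)
        assert ev2.r == pytest.approx(-1.0)

    def test_hand_computed_r_and_mae(self):
        ev = pc.evaluate_predictions([1.0, 3.0, 2.0], [1.0, 2.0, 3.0])
        assert ev.r == pytest.approx(0.5, abs=1e-12)
        assert ev.mae == pytest.approx(1.0, abs=1e-12)

    def test_constant_chronological_rejected(self):
        with pytest.raises(ValueError):
            pc.evaluate_predictions([1.0, 2.0], [5.0, 5.0])
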