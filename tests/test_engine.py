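"""Likelihood correctness, sufficient statistics and ML fitting."""

import numpy as np
import pandas as pd
import pytest

import clusterbias as cb
from clusterbias import engine
from clusterbias.engine import ImpliedMoments

from conftest import random_tiny_instance
from oracles import anova_ml_variance_components, dense_loglik


class TestPreprocess:
    def _toy_frame(self, n_rows=12):
        rng = np.random.default_rng(0)
        half = n_rows // 2
        return pd.DataFrame(
            {
                "school": np.repeat(["A", "B"], half),
                "class": np.concatenate(
                    [np.tile(["c1", "c2"], half // 2), np.tile(["c3", "c4"], half // 2)]
                ),
                "x1": rng.normal(size=n_rows),
                "x2": rng.normal(size=n_rows),
            }
        )

    def test_basic_shapes_and_summary(self):
        df = self._toy_frame()
        data = cb.preprocess(df, "school", "class", ["x1", "x2"])
        assert data.n == 12 and data.p == 2
        s = data.summary()
        assert s["n_schools"] == 2 and s["n_classes"] == 4
        assert s["mean_class_size"] == pytest.approx(3.0)

    def test_missing_indicator_rows_dropped(self):
        df = self._toy_frame()
        df.loc[0, "x1"] = np.nan
        data = cb.preprocess(df, "school", "class", ["x1", "x2"])
        assert data.n == 11

    def test_pool_policy_creates_one_pseudo_class_per_school(self):
        df = self._toy_frame()
        df.loc[df["school"] == "B", "class"] = None
        data = cb.preprocess(df, "school", "class", ["x1", "x2"], "pool")
        df_out = data.to_dataframe()
        assert df_out[df_out["school"] == "B"]["class"].nunique() == 1
        assert data.summary()["n_classes"] == 3

    def test_drop_policy(self):
        df = self._toy_frame()
        df.loc[df["school"] == "B", "class"] = None
        data = cb.preprocess(df, "school", "class", ["x1", "x2"], "drop")
        assert data.n == 6

    def test_class_label_spanning_schools_rejected(self):
        df = self._toy_frame()
        df.loc[df["school"] == "B", "class"] = "c1"  # c1 now under A and B
        with pytest.raises(ValueError, match="c1"):
            cb.preprocess(df, "school", "class", ["x1", "x2"])

    def test_single_row_dataset_is_valid(self):
        df = pd.DataFrame({"school": ["A"], "class": ["c"], "x": [1.0]})
        data = cb.preprocess(df, "school", "class", ["x"])
        assert data.n == 1 and data.summary()["mean_class_size"] == 1.0

    def test_missing_column_named_in_error(self):
        df = self._toy_frame()
        with pytest.raises(KeyError, match="x9"):
            cb.preprocess(df, "school", "class", ["x1", "x9"])

    def test_two_level_mode_without_school(self):
        df = self._toy_frame()
        data = cb.preprocess(df, None, "class", ["x1", "x2"])
        assert data.n_levels == 2 and data.school_id is None


class TestSufficientStats:
    def test_conservation_and_identical_rows(self):
        y = np.array([[1.0, 2.0], [1.0, 2.0]])
        data = cb.HierarchicalData(y, np.array(["c", "c"]), None, ("a", "b"))
        stats = cb.compute_sufficient_stats(data)
        assert stats.class_sizes.sum() == data.n
        np.testing.assert_allclose(stats.class_means[0], y[0])
        np.testing.assert_allclose(stats.s_w, 0.0, atol=1e-12)

    def test_weighted_class_means_reproduce_grand_mean(self):
        rng = np.random.default_rng(3)
        data, _ = random_tiny_instance(rng)
        stats = cb.compute_sufficient_stats(data)
        np.testing.assert_allclose(stats.grand_mean, data.indicators.mean(axis=0))

    def test_reduction_is_lossless_for_the_likelihood(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            data, moments = random_tiny_instance(rng)
            stats = cb.compute_sufficient_stats(data)
            assert cb.loglik(stats, moments) == pytest.approx(
                dense_loglik(data, moments), abs=1e-8
            )


class TestImpliedMoments:
    def test_zero_loadings_identity_residuals(self):
        models = cb.build_cluster_bias_models(3, [])
        spec = models.baseline
        compiled = engine.compile_spec(spec)
        theta = np.zeros(compiled.n_free)
        for i, row in enumerate(compiled.table.rows):
            if row.slots[0].matrix == "theta":
                theta[i] = 1.0
        mo = cb.implied_moments(spec, theta)
        np.testing.assert_allclose(mo.sigma_by_level[0], np.eye(3))

    def test_closed_form_two_indicator(self):
        # lambda = (1,1)', phi = 1, Theta = I  =>  Sigma = [[2,1],[1,2]]
        from clusterbias.model_spec import Fixed, Free, LevelModel, LoadingPattern, ModelSpec

        loadings = LoadingPattern(((Fixed(1.0),), (Fixed(1.0),)), ("a", "b"), ("g",))
        lv = LevelModel(1, loadings, ((Fixed(1.0),),), (Fixed(1.0), Fixed(1.0)))
        spec = ModelSpec((lv,), (Fixed(0.0), Fixed(0.0)))
        mo = cb.implied_moments(spec, np.array([]))
        np.testing.assert_allclose(mo.sigma_by_level[0], [[2, 1], [1, 2]])

    def test_constrained_level3_is_low_rank(self):
        models = cb.build_cluster_bias_models(8, [{0, 1}])
        compiled = engine.compile_spec(models.level3_constrained)
        rng = np.random.default_rng(0)
        theta = np.abs(rng.normal(0.5, 0.2, compiled.n_free))
        mo = compiled.moments(theta)
        rank = np.linalg.matrix_rank(mo.sigma_by_level[2], tol=1e-10)
        assert rank <= 2  # common factor + doublet factor

    def test_nonfinite_theta_rejected(self):
        models = cb.build_cluster_bias_models(3, [])
        compiled = engine.compile_spec(models.baseline)
        theta = np.zeros(compiled.n_free)
        theta[0] = np.nan
        with pytest.raises(ValueError):
            compiled.moments(theta)


class TestLoglik:
    def test_matches_dense_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            data, moments = random_tiny_instance(rng, n_levels=3)
            stats = cb.compute_sufficient_stats(data)
            assert cb.loglik(stats, moments) == pytest.approx(
                dense_loglik(data, moments), abs=1e-8
            )

    def test_two_level_matches_dense_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            data, moments = random_tiny_instance(rng, n_levels=2)
            stats = cb.compute_sufficient_stats(data)
            assert cb.loglik(stats, moments) == pytest.approx(
                dense_loglik(data, moments), abs=1e-8
            )

    def test_single_observation_collapses_to_mvn(self):
        from scipy.stats import multivariate_normal

        y = np.array([[0.3, -0.2]])
        data = cb.HierarchicalData(y, np.array(["c"]), np.array(["s"]), ("a", "b"))
        stats = cb.compute_sufficient_stats(data)
        S1, S2, S3 = np.eye(2), 0.5 * np.eye(2), 0.25 * np.eye(2)
        mo = ImpliedMoments(np.zeros(2), [S1, S2, S3])
        expected = multivariate_normal.logpdf(y[0], np.zeros(2), S1 + S2 + S3)
        assert cb.loglik(stats, mo) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_row_permutation_within_class(self):
        rng = np.random.default_rng(5)
        data, moments = random_tiny_instance(rng)
        perm = rng.permutation(data.n)
        shuffled = cb.HierarchicalData(
            data.indicators[perm],
            data.class_id[perm],
            data.school_id[perm],
            data.indicator_names,
        )
        a = cb.loglik(cb.compute_sufficient_stats(data), moments)
        b = cb.loglik(cb.compute_sufficient_stats(shuffled), moments)
        assert a == pytest.approx(b, abs=1e-8)

    def test_zero_sigma3_equals_two_level_likelihood(self):
        rng = np.random.default_rng(6)
        data, moments = random_tiny_instance(rng, n_levels=3)
        p = data.p
        mo3 = ImpliedMoments(moments.mu, [moments.sigma_by_level[0], moments.sigma_by_level[1], np.zeros((p, p))])
        mo2 = ImpliedMoments(moments.mu, moments.sigma_by_level[:2])
        data2 = cb.HierarchicalData(data.indicators, data.class_id, None, data.indicator_names)
        ll3 = cb.loglik(cb.compute_sufficient_stats(data), mo3)
        ll2 = cb.loglik(cb.compute_sufficient_stats(data2), mo2)
        assert ll3 == pytest.approx(ll2, abs=1e-8)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        data, moments = random_tiny_instance(rng)
        c = 2.5
        scaled = cb.HierarchicalData(
            data.indicators * c, data.class_id, data.school_id, data.indicator_names
        )
        mo_scaled = ImpliedMoments(
            moments.mu * c, [s * c * c for s in moments.sigma_by_level]
        )
        ll = cb.loglik(cb.compute_sufficient_stats(data), moments)
        ll_scaled = cb.loglik(cb.compute_sufficient_stats(scaled), mo_scaled)
        assert ll_scaled == pytest.approx(ll - data.n * data.p * np.log(c), rel=1e-9)

    def test_singular_sigma1_gives_minus_inf(self):
        rng = np.random.default_rng(8)
        data, moments = random_tiny_instance(rng)
        p = data.p
        bad = ImpliedMoments(moments.mu, [np.zeros((p, p))] + moments.sigma_by_level[1:])
        assert cb.loglik(cb.compute_sufficient_stats(data), bad) == -np.inf


class TestFitML:
    def test_variance_components_match_anova_closed_form(self):
        """p=1 balanced two-level saturated fit vs textbook ML estimators."""
        rng = np.random.default_rng(21)
        C, n = 40, 8
        b = rng.normal(0, np.sqrt(0.4), C)
        y = (1.5 + np.repeat(b, n) + rng.normal(0, np.sqrt(0.9), C * n))
        group = np.repeat([f"c{i}" for i in range(C)], n)
        data = cb.HierarchicalData(y[:, None], group, None, ("y",))
        fit = cb.fit_saturated(data, 2)
        assert fit.converged
        mu_hat, se2_hat, sb2_hat = anova_ml_variance_components(y, group)
        est = fit.estimates_by_label()
        assert est["nu1"] == pytest.approx(mu_hat, abs=1e-4)
        assert est["s1_1_1"] == pytest.approx(se2_hat, rel=1e-3)
        assert est["s2_1_1"] == pytest.approx(sb2_hat, rel=1e-3, abs=1e-4)

    def test_single_level_saturated_closed_form(self):
        rng = np.random.default_rng(22)
        y = rng.normal(size=(60, 2)) @ np.array([[1.0, 0.4], [0.0, 0.9]])
        data = cb.HierarchicalData(y, np.array([f"r{i}" for i in range(60)]), None, ("a", "b"))
        fit = cb.fit_saturated(data, 1)
        assert fit.converged
        est = fit.estimates_by_label()
        ml_cov = np.cov(y, rowvar=False, bias=True)
        assert est["nu1"] == pytest.approx(y[:, 0].mean(), abs=1e-5)
        assert est["s1_1_1"] == pytest.approx(ml_cov[0, 0], rel=1e-4)
        assert est["s1_2_1"] == pytest.approx(ml_cov[1, 0], rel=1e-4, abs=1e-5)

    def test_parameter_recovery(self, recovery_design, recovery_fit):
        est = recovery_fit.estimates_by_label()
        for j, lam in enumerate(recovery_design.loadings):
            assert est[f"lam{j + 1}"] == pytest.approx(lam, abs=0.05)
        assert est["phi2"] == pytest.approx(0.3, abs=0.1)

    def test_deterministic_given_seed(self, recovery_data):
        spec = cb.build_cluster_bias_models(4, []).baseline
        f1 = cb.fit_ml(spec, recovery_data, cb.FitOptions(seed=3))
        f2 = cb.fit_ml(spec, recovery_data, cb.FitOptions(seed=3))
        np.testing.assert_array_equal(f1.estimates, f2.estimates)

    def test_null_level3_residuals_pile_at_boundary(self, small_null_design):
        data = cb.simulate_dataset(small_null_design, seed=42)
        fit = cb.fit_ml(cb.build_cluster_bias_models(4, []).baseline, data)
        assert fit.converged
        theta3 = [fit.estimate(f"theta{j + 1}_l3") for j in range(4)]
        assert np.median(theta3) == pytest.approx(0.0, abs=1e-4)
        assert fit.boundary.any()

    def test_nesting_monotonicity(self, recovery_data):
        models = cb.build_cluster_bias_models(4, [])
        stats = cb.compute_sufficient_stats(recovery_data)
        sat = cb.fit_saturated(stats, 3)
        base = cb.fit_ml(models.baseline, stats)
        constrained = cb.fit_ml(models.level2_constrained, stats)
        indep = cb.fit_independence(stats, 3)
        assert sat.loglik >= base.loglik >= constrained.loglik - 1e-6
        assert sat.loglik >= indep.loglik

    def test_mismatched_spec_and_data_rejected(self, recovery_data):
        with pytest.raises(ValueError):
            cb.fit_ml(cb.build_cluster_bias_models(5, []).baseline, recovery_data)
        data2 = cb.HierarchicalData(
            recovery_data.indicators,
            recovery_data.class_id,
            None,
            recovery_data.indicator_names,
        )
        with pytest.raises(ValueError, match="school"):
            cb.fit_ml(cb.build_cluster_bias_models(4, []).baseline, data2)


class TestStandardErrors:
    def test_se_reasonable_and_boundary_flagged(self, small_null_design):
        data = cb.simulate_dataset(small_null_design, seed=9)
        stats = cb.compute_sufficient_stats(data)
        fit = cb.fit_ml(cb.build_cluster_bias_models(4, []).baseline, stats)
        cb.standard_errors(fit, stats)
        df = fit.to_frame()
        loads = df[df["matrix"] == "lambda"]
        assert np.isfinite(loads["se"]).all() and (loads["se"] > 0).all()
        # true loadings inside +-3 SE
        for j, lam in enumerate(small_null_design.loadings):
            row = df[df["label"] == f"lam{j + 1}"].iloc[0]
            assert abs(row["estimate"] - lam) < 3 * row["se"] + 1e-12
        # boundary-pinned variances carry a flag, not an SE
        pinned = df[df["at_boundary"]]
        assert len(pinned) > 0
        assert pinned["se"].isna().all()

    def test_requires_matching_data(self, small_null_design):
        data = cb.simulate_dataset(small_null_design, seed=9)
        other = cb.simulate_dataset(small_null_design, seed=10)
        fit = cb.fit_ml(cb.build_cluster_bias_models(4, []).baseline, data)
        with pytest.raises(ValueError, match="data"):
            cb.standard_errors(fit, other)
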