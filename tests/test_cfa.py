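"""FIML confirmatory factor analysis: deviance, fitting, model comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.stats import multivariate_normal
from sklearn.base import clone

import ftcdlat as fl
from ftcdlat.cfa import (
    CFAModelSpec,
    _GroupData,
    akaike_weights,
    build_spec,
    fiml_deviance,
    fit,
    fit_independence,
    fit_indices,
    fit_nested_pair,
    fit_saturated,
    leave_one_out,
    likelihood_ratio_test,
    lrt_from_deviances,
    mx_aic,
    mx_bic,
)
from ftcdlat.synthetic import LatentModelConfig, one_factor_group, strong_two_factor_group


def _frame(X):
    return pd.DataFrame(np.asarray(X, float), columns=fl.INDICATORS)


def _random_params(spec, rng):
    vals = []
    for name in spec.param_names():
        if name.startswith("l"):
            vals.append(rng.uniform(0.2, 0.9))
        elif name.startswith(("psi", "theta")):
            vals.append(rng.uniform(0.5, 2.0))
        else:
            vals.append(rng.uniform(-1, 3))
    return np.array(vals)


class TestSpec:
    @pytest.mark.parametrize(
        "factors,groups,shared,expected",
        [
            (1, "single", True, 18),
            (2, "single", True, 23),
            (2, ("left", "right"), True, 36),
            (2, ("left", "right"), False, 46),
        ],
    )
    def test_free_parameter_counts(self, factors, groups, shared, expected):
        spec = build_spec(factors, groups=groups, shared_loadings=shared)
        assert spec.count_free_parameters() == expected
        assert len(spec.param_names()) == expected

    def test_multigroup_one_factor_unsupported(self):
        with pytest.raises(ValueError):
            build_spec(1, groups=("left", "right"))

    def test_session_equality_in_implied_moments(self):
        spec = build_spec(2, "single")
        rng = np.random.default_rng(0)
        mu, sigma = spec.implied_moments(_random_params(spec, rng))["all"]
        # session-tied structure: both session blocks are identical
        assert np.allclose(mu[:6], mu[6:])
        assert np.allclose(sigma[:6, :6], sigma[6:, 6:])
        evals = np.linalg.eigvalsh(sigma)
        assert evals.min() > 0

    def test_yaml_dict_records_fixed_constraints(self):
        d = build_spec(2, "single").to_yaml_dict()
        assert d["fixed"]["marker_loadings"] == [1.0, 0.0]
        assert d["fixed"]["factor2_variance"] == 1.0
        assert d["n_free_parameters"] == 23


class TestFIMLDeviance:
    def test_matches_bruteforce_marginal_mvn(self):
        rng = np.random.default_rng(1)
        spec = build_spec(2, "single")
        params = _random_params(spec, rng)
        X = rng.normal(1.0, 1.5, (30, 12))
        X[rng.random((30, 12)) < 0.07] = np.nan
        dev = fiml_deviance(spec, params, _frame(X))
        mu, sigma = spec.implied_moments(params)["all"]
        brute = 0.0
        for row in X:
            o = np.isfinite(row)
            brute += -2 * multivariate_normal.logpdf(row[o], mu[o], sigma[np.ix_(o, o)])
        assert dev == pytest.approx(brute, abs=1e-8)

    def test_single_missing_cell_equals_marginal_density(self):
        rng = np.random.default_rng(2)
        spec = build_spec(2, "single")
        params = _random_params(spec, rng)
        row = rng.normal(1.0, 1.0, 12)
        row[4] = np.nan
        dev = fiml_deviance(spec, params, _frame(row[None, :]))
        mu, sigma = spec.implied_moments(params)["all"]
        o = np.isfinite(row)
        expected = -2 * multivariate_normal.logpdf(row[o], mu[o], sigma[np.ix_(o, o)])
        assert dev == pytest.approx(expected, abs=1e-10)

    def test_duplicating_rows_doubles_deviance(self):
        rng = np.random.default_rng(3)
        spec = build_spec(1, "single")
        params = _random_params(spec, rng)
        X = rng.normal(0, 1, (10, 12))
        one = fiml_deviance(spec, params, _frame(X))
        two = fiml_deviance(spec, params, _frame(np.vstack([X, X])))
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_dict_and_vector_params_agree(self):
        rng = np.random.default_rng(4)
        spec = build_spec(2, "single")
        params = _random_params(spec, rng)
        X = rng.normal(0, 1, (8, 12))
        as_dict = dict(zip(spec.param_names(), params))
        assert fiml_deviance(spec, params, _frame(X)) == fiml_deviance(
            spec, as_dict, _frame(X)
        )

    def test_singular_covariance_penalized_not_fatal(self):
        spec = build_spec(2, "single")
        params = np.array(
            [0.0 if n.startswith(("l", "theta", "psi")) else 0.0 for n in spec.param_names()]
        )
        X = np.random.default_rng(5).normal(0, 1, (5, 12))
        dev = fiml_deviance(spec, params, _frame(X))
        assert dev > 1e10  # penalty, no exception

    def test_all_missing_row_rejected(self):
        X = np.full((2, 12), np.nan)
        X[0] = 1.0
        with pytest.raises(ValueError, match="at least one observed"):
            _GroupData(X)


class TestSaturatedAndBaseline:
    def test_complete_data_saturated_equals_closed_form(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (40, 12))
        sat = fit_saturated(_frame(X))
        S = np.cov(X.T, bias=True)
        closed = 40 * (12 * np.log(2 * np.pi) + np.linalg.slogdet(S)[1] + 12)
        assert sat.deviance == pytest.approx(closed, abs=1e-8)
        assert sat.n_free == 90

    def test_em_beats_available_case_moments(self):
        rng = np.random.default_rng(7)
        X = rng.multivariate_normal(np.zeros(12), np.eye(12) + 0.5, size=60)
        X[rng.random((60, 12)) < 0.1] = np.nan
        sat = fit_saturated(_frame(X))
        gd = _GroupData(X)
        mu0 = np.nanmean(X, axis=0)
        sig0 = np.diag(np.nanvar(X, axis=0))
        assert sat.deviance <= gd.deviance(mu0, sig0)

    def test_independence_matches_univariate_normal_deviances(self):
        rng = np.random.default_rng(8)
        X = rng.normal(2, 1.5, (25, 12))
        X[0, 3] = np.nan
        ind = fit_independence(_frame(X))
        brute = 0.0
        for j in range(12):
            col = X[:, j]
            col = col[np.isfinite(col)]
            brute += -2 * sps.norm.logpdf(col, col.mean(), col.std()).sum()
        assert ind.deviance == pytest.approx(brute, rel=1e-10)
        assert ind.n_free == 24


class TestFit:
    def test_two_factor_recovery(self):
        g = strong_two_factor_group(n=200)
        tab = fl.generate_li_table(LatentModelConfig(groups=[g], seed=7))
        res = fit(build_spec(2, "single"), tab.values, starts=5, seed=0, compute_se=False)
        assert res.converged
        lam = res.loadings()
        est2 = lam["factor2"].to_numpy()
        if np.sum(est2 * g.loadings_f2) < 0:  # factor-2 sign is arbitrary
            est2 = -est2
        assert np.all(np.abs(lam["factor1"].to_numpy() - g.loadings_f1) < 0.15)
        assert np.all(np.abs(est2 - g.loadings_f2) < 0.15)
        theta_hat = np.array([res.param_dict[f"theta_{t}@all"] for t in fl.TASKS])
        assert np.all(np.abs(theta_hat - g.residual_vars) / g.residual_vars < 0.20)

    def test_determinism_under_seed(self, study_table):
        sub = study_table.group_values("right")
        a = fit(build_spec(2, "single"), sub, starts=3, seed=5, compute_se=False)
        b = fit(build_spec(2, "single"), sub, starts=3, seed=5, compute_se=False)
        assert np.array_equal(a.params, b.params)

    def test_df_bookkeeping_complete_and_missing(self):
        rng = np.random.default_rng(9)
        X = rng.normal(1, 1, (30, 12))
        spec = build_spec(2, "single")
        res = fit(spec, _frame(X), starts=2, seed=0, compute_se=False)
        assert res.df == 12 * 30 - 23
        X2 = X.copy()
        X2[0, 0] = np.nan
        res2 = fit(spec, _frame(X2), starts=2, seed=0, compute_se=False)
        assert res2.df == res.df - 1

    def test_wald_se_reported_for_free_loadings(self, study_table):
        sub = study_table.group_values("left")
        res = fit(build_spec(2, "single"), sub, starts=2, seed=0, compute_se=True)
        tbl = res.loading_table()
        assert len(tbl) == 10  # 5 free tasks x 2 factors
        assert (tbl["se"].dropna() > 0).all()
        assert (tbl["ci_low"] <= tbl["estimate"]).all()
        assert (tbl["ci_high"] >= tbl["estimate"]).all()

    def test_nested_deviance_ordering(self, study_table):
        sub = study_table.group_values("left")
        small, large, _ = fit_nested_pair(
            sub, build_spec(1, "single"), build_spec(2, "single"), starts=2, seed=0
        )
        assert large.deviance <= small.deviance + 1e-6
        con, unc, _ = fit_nested_pair(
            study_table,
            build_spec(2, ("left", "right"), shared_loadings=True),
            build_spec(2, ("left", "right"), shared_loadings=False),
            starts=2,
            seed=0,
        )
        assert unc.deviance <= con.deviance + 1e-6

    def test_multigroup_groups_use_own_moments(self, study_table):
        spec = build_spec(2, ("left", "right"), shared_loadings=False)
        res = fit(spec, study_table, starts=2, seed=0, compute_se=False)
        mu_l, _ = res.implied["left"]
        mu_r, _ = res.implied["right"]
        assert not np.allclose(mu_l, mu_r)  # groups have distinct means

    def test_too_few_rows_rejected(self):
        X = np.random.default_rng(0).normal(0, 1, (1, 12))
        with pytest.raises(ValueError, match="observed cells"):
            fit(build_spec(2, "single"), _frame(X), starts=1)


class TestModelComparison:
    def test_chi_square_p_from_printed_deviances(self):
        stat, df, p = lrt_from_deviances(1204.239, 1128.909, 5)
        assert stat == pytest.approx(75.33, abs=0.001)
        assert p == pytest.approx(7.93e-15, rel=0.005)
        _, _, p2 = lrt_from_deviances(1555.086, 1536.077, 5)
        assert p2 == pytest.approx(0.0019, abs=5e-5)
        stat3, _, p3 = lrt_from_deviances(2688.054, 2664.986, 10)
        assert stat3 == pytest.approx(23.07, abs=0.005)
        assert p3 == pytest.approx(0.0105, abs=5e-5)

    def test_mx_information_criteria_match_printed_values(self):
        assert mx_aic(1204.239, 351) == pytest.approx(502.24, abs=0.005)
        assert mx_bic(1204.239, 351, 31) == pytest.approx(-1.09, abs=0.005)

    def test_akaike_weights_printed_pairs(self):
        w = akaike_weights([569.09, 560.08])
        assert w[0] == pytest.approx(0.01, abs=0.005)
        assert w[1] == pytest.approx(0.99, abs=0.005)
        w2 = akaike_weights([1000.05, 996.99])
        assert w2[0] == pytest.approx(0.18, abs=0.005)
        assert w2[1] == pytest.approx(0.82, abs=0.005)

    def test_equal_aics_equal_weights(self):
        assert np.allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])

    @given(st.lists(st.floats(min_value=-500, max_value=500), min_size=2, max_size=6),
           st.floats(min_value=-100, max_value=100))
    def test_akaike_weight_properties(self, aics, shift):
        w = akaike_weights(aics)
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()
        assert np.allclose(akaike_weights(np.asarray(aics) + shift), w)

    def test_fit_indices_perfect_fit_limit(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 1, (40, 12))
        sat = fit_saturated(_frame(X))
        ind = fit_independence(_frame(X))
        # a "model" with the saturated deviance but fewer parameters
        fake = fit_saturated(_frame(X))
        fake.n_free = 23
        out = fit_indices(fake, sat, ind)
        assert out["cfi"] == 1.0 and out["rmsea"] == 0.0

    def test_fit_indices_consistency_error(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (30, 12))
        sat = fit_saturated(_frame(X))
        ind = fit_independence(_frame(X))
        bad = fit_saturated(_frame(X))
        bad.deviance = sat.deviance - 5.0
        bad.n_free = 23
        with pytest.raises(ValueError, match="exceeds"):
            fit_indices(bad, sat, ind)

    def test_fit_indices_on_fitted_model(self, study_table):
        sub = study_table.group_values("right")
        res = fit(build_spec(2, "single"), sub, starts=2, seed=0, compute_se=False)
        out = fit_indices(res, fit_saturated(sub), fit_independence(sub))
        assert out["aic"] == pytest.approx(mx_aic(res.deviance, res.df))
        assert 0 <= out["cfi"] <= 1 and out["rmsea"] >= 0
        # the generating model is two-factor, so the fit should be decent
        assert out["cfi"] > 0.85

    def test_non_nested_lrt_rejected(self, study_table):
        sub = study_table.group_values("left")
        a = fit(build_spec(2, "single"), sub, starts=1, seed=0, compute_se=False)
        b = fit(build_spec(2, ("left", "right"), shared_loadings=True), study_table,
                starts=1, seed=0, compute_se=False)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(a, b)


class TestLeaveOneOut:
    def test_iteration_count_and_strong_two_factor_stability(self):
        g = strong_two_factor_group(n=40)
        tab = fl.generate_li_table(LatentModelConfig(groups=[g], seed=17))
        out = leave_one_out(
            tab.values, build_spec(1, "single"), build_spec(2, "single"),
            starts=1, seed=0,
        )
        assert out["n_iterations"] == 40
        assert all(r["converged"] for r in out["iterations"])
        # clearly two-factor data: every iteration prefers the larger model
        assert out["n_significant"] == 40

    def test_minimum_rows_enforced(self):
        X = np.random.default_rng(0).normal(0, 1, (5, 12))
        with pytest.raises(ValueError, match="at least 10"):
            leave_one_out(_frame(X), build_spec(1, "single"), build_spec(2, "single"))


class TestEstimatorSurface:
    def test_sklearn_contract(self, study_table):
        est = fl.ConfirmatoryFactorModel(n_factors=2, n_starts=2, seed=0, compute_se=False)
        cloned = clone(est)
        assert cloned.get_params()["n_factors"] == 2
        cloned.set_params(n_factors=1)
        assert cloned.get_params()["n_factors"] == 1
        fitted = est.fit(study_table.group_values("right"))
        assert fitted is est
        assert hasattr(est, "deviance_") and hasattr(est, "loadings_")
        assert est.df_ == est.n_obs_cells_ - 23
        assert est.loadings_["all"].loc["D", "factor1"] == 1.0

    def test_multigroup_estimator(self, study_table):
        est = fl.ConfirmatoryFactorModel(
            n_factors=2, multigroup=True, shared_loadings=False,
            n_starts=2, seed=0, compute_se=False,
        ).fit(study_table)
        assert set(est.loadings_) == {"left", "right"}
        assert est.result_.n_free == 46

    def test_score_is_mean_loglik_per_row(self, study_table):
        sub = study_table.group_values("right")
        est = fl.ConfirmatoryFactorModel(n_starts=2, seed=0, compute_se=False).fit(sub)
        s = est.score(sub)
        assert s == pytest.approx(-0.5 * est.deviance_ / len(sub))
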