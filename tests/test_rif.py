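"""Recentred influence functions, the design matrix, the two-level fit and
Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from healthineq import (GeneratorConfig, RIFDecomposition, build_design_matrix,
                        erreygers_ci, fit_two_level, generate_macro,
                        generate_microdata, pool_rubin, rif_erreygers,
                        rif_standard, standard_ci)
from healthineq.pipeline import macro_quartile_table
from healthineq.rif import DecompositionResult
from conftest import random_binary_sample


class TestRIFValues:
    def test_toy_erreygers_hand_values(self, toy_sample):
        h, y, w = toy_sample
        np.testing.assert_allclose(rif_erreygers(h, y, w), [-1, -1, -1, -1])

    def test_toy_standard_hand_values(self, toy_sample):
        h, y, w = toy_sample
        np.testing.assert_allclose(rif_standard(h, y, w), [0, 0, -1, -1])

    def test_constant_outcome_mean_rif_is_zero(self):
        h = np.ones(6)
        y = np.arange(6.0)
        assert np.mean(rif_erreygers(h, y)) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 10_000))
    def test_weighted_mean_equals_index_with_ties(self, seed):
        """mean(RIF) = index exactly under the block-midpoint tie convention."""
        rng = np.random.default_rng(seed)
        h, y, w = random_binary_sample(rng, allow_ties=True)
        E = erreygers_ci(h, y, w).value
        assert abs(np.average(rif_erreygers(h, y, w), weights=w) - E) < 1e-9
        mu = np.average(h, weights=w)
        if mu > 0:
            C = standard_ci(h, y, w).value
            assert abs(np.average(rif_standard(h, y, w), weights=w) - C) < 1e-9

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_erreygers_standard_rif_relation(self, seed):
        """RIF_E = 4*mu*RIF_C + 4*C*(h - mu): differentiating E = 4*mu*C."""
        rng = np.random.default_rng(seed)
        h, y, w = random_binary_sample(rng)
        mu = np.average(h, weights=w)
        if mu == 0:
            return
        C = standard_ci(h, y, w).value
        lhs = rif_erreygers(h, y, w)
        rhs = 4 * mu * rif_standard(h, y, w) + 4 * C * (h - mu)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_gateaux_first_order_with_quadratic_residual(self):
        """Perturbing one weight changes the index by eps*w_i*(RIF_i - E)/W
        to first order, with the residual shrinking like eps^2."""
        rng = np.random.default_rng(7)
        h = rng.integers(0, 2, 40).astype(float)
        y = rng.normal(size=40)
        w = rng.uniform(0.5, 2.0, 40)
        E = erreygers_ci(h, y, w).value
        rif = rif_erreygers(h, y, w)
        W = w.sum()
        for i in (0, 13, 39):
            resid = []
            for eps in (1e-3, 5e-4):
                w2 = w.copy()
                w2[i] *= 1 + eps
                dE = erreygers_ci(h, y, w2).value - E
                lin = eps * w[i] * (rif[i] - E) / W
                assert abs(dE - lin) < 50 * eps**2
                resid.append(abs(dE - lin))
            if resid[0] > 1e-12:
                assert 3.0 < resid[0] / resid[1] < 5.0

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError):
            rif_erreygers(np.array([0.0, 0.5]), np.array([1.0, 2.0]))


class TestDesignMatrix:
    def test_column_count_and_coding(self, small_cohort):
        micro, macro, _ = small_cohort
        macro33 = generate_macro(GeneratorConfig(n_countries=33, seed=4))
        micro33 = generate_microdata(
            GeneratorConfig(n_countries=33, persons_per_country=60, seed=4))
        X = build_design_matrix(micro33, macro_quartile_table(macro33))
        assert X.shape[1] == 31
        person = micro33.iloc[[0]].assign(
            age_years=62, age_band="60-64", marital="married",
            education="tertiary", gender="male")
        Xp = build_design_matrix(person, macro_quartile_table(macro33))
        indiv = [c for c in Xp.columns if "[Q" not in c]
        set_cols = {c for c in indiv if Xp.iloc[0][c] == 1} - {"chronic", "smoke", "drink"}
        assert set_cols == {"age_band[60-64]", "education[tertiary]"}

    def test_full_rank_on_populated_cells(self):
        cfg = GeneratorConfig(n_countries=33, persons_per_country=80, seed=2)
        micro = generate_microdata(cfg)
        X = build_design_matrix(micro, macro_quartile_table(generate_macro(cfg)))
        assert np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]

    def test_unseen_category_rejected(self, small_cohort):
        micro, macro, _ = small_cohort
        bad = micro.head(20).copy()
        bad.loc[bad.index[0], "education"] = "college"
        with pytest.raises(ValueError, match="unseen category"):
            build_design_matrix(bad, macro_quartile_table(macro),
                                macro_variables=["gdp"])

    def test_missing_covariates_rejected(self, small_cohort):
        micro, macro, _ = small_cohort
        bad = micro.head(20).copy()
        bad.loc[bad.index[0], "education"] = np.nan
        with pytest.raises(ValueError, match="impute first"):
            build_design_matrix(bad, macro_quartile_table(macro),
                                macro_variables=["gdp"])


class TestTwoLevelFit:
    def test_recovers_known_coefficients(self):
        """Random-intercept REML on y = X*beta + u_country + eps recovers
        every coefficient to within 3 standard errors."""
        rng = np.random.default_rng(21)
        n_c, n_p = 20, 500
        groups = np.repeat(np.arange(n_c), n_p)
        X = pd.DataFrame({
            "x1": rng.normal(size=n_c * n_p),
            "x2": rng.integers(0, 2, n_c * n_p).astype(float),
        })
        beta = {"Intercept": -0.1, "x1": 0.05, "x2": -0.08}
        u = rng.normal(0, 0.05, n_c)[groups]
        y = (beta["Intercept"] + beta["x1"] * X["x1"] + beta["x2"] * X["x2"]
             + u + rng.normal(0, 0.3, n_c * n_p))
        res = fit_two_level(y.to_numpy(), X, groups)
        assert res.model == "random-intercept"
        for term, true in beta.items():
            est = res.terms.loc[term]
            assert abs(est["estimate"] - true) < 3 * est["se"]

    def test_intercept_only_returns_mean(self):
        """With an empty covariate set the fitted intercept is the weighted
        mean of the response — the regression identity behind mean(RIF) = E."""
        rng = np.random.default_rng(5)
        groups = np.repeat(np.arange(6), 50)
        y = rng.normal(size=300) + 0.1 * groups
        res = fit_two_level(y, pd.DataFrame(index=range(300)), groups)
        assert res.terms.loc["Intercept", "estimate"] == pytest.approx(
            y.mean(), abs=1e-8)
        w = rng.uniform(0.5, 2.0, 300)
        res_w = fit_two_level(y, pd.DataFrame(index=range(300)), groups,
                              weights=w, model="cluster-robust")
        assert res_w.terms.loc["Intercept", "estimate"] == pytest.approx(
            np.average(y, weights=w), abs=1e-10)

    def test_duplicate_column_raises_listing_alias(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=200)})
        X["b"] = X["a"]
        with pytest.raises(ValueError, match=r"aliased.*\['b'\]"):
            fit_two_level(rng.normal(size=200), X, np.repeat(np.arange(4), 50))

    def test_too_few_countries_rejected(self):
        with pytest.raises(ValueError, match="4 countries"):
            fit_two_level(np.zeros(30), pd.DataFrame({"x": np.arange(30.0)}),
                          np.repeat([0, 1, 2], 10))

    def test_boundary_collapse_falls_back_to_cluster_robust(self):
        rng = np.random.default_rng(9)
        groups = np.repeat(np.arange(8), 40)  # no true country effect
        y = rng.normal(size=320)
        est = RIFDecomposition().fit(pd.DataFrame({"x": rng.normal(size=320)}),
                                     y, groups)
        assert est.model_used_ in ("random-intercept",
                                   "cluster-robust (boundary fallback)")
        # forcing the cluster-robust model always works and honors weights
        est2 = RIFDecomposition(model="cluster-robust").fit(
            pd.DataFrame({"x": rng.normal(size=320)}), y, groups,
            sample_weight=rng.uniform(0.5, 2, 320))
        assert est2.model_used_ == "cluster-robust"


def test_end_to_end_gradient_flattening_covariate_direction():
    """When tertiary education removes the income-disability gradient for its
    holders, its pooled decomposition coefficient is significant and moves
    the (negative, pro-poor) index toward zero — i.e. it is positive on the
    index scale, the direction associated with reduced pro-poor inequality."""
    from healthineq.pipeline import decompose_domain

    co = {"rank": -1.2, "education": -0.35, "chronic": 0.6, "age_trend": 0.25,
          "country_sd": 0.15, "education_rank_gradient": 0.8,
          "education_attenuation": 1.0}
    cfg = GeneratorConfig(n_countries=20, persons_per_country=2000,
                          dgp_mode="logistic", logit_coefficients=co, seed=40)
    res = decompose_domain(generate_microdata(cfg), generate_macro(cfg),
                           "adl", macro_variables=["gdp"])
    tert = res.terms.loc["education[tertiary]"]
    assert tert["estimate"] > 0
    assert tert["p_value"] < 0.05


def _result(estimates, ses, n=1000, n_countries=10):
    terms = pd.DataFrame({
        "estimate": estimates, "se": ses,
        "p_value": np.clip(np.abs(estimates) * 0, 0, 1) + 0.5,
    }, index=[f"t{i}" for i in range(len(estimates))])
    return DecompositionResult(terms=terms, model="random-intercept",
                               n_persons=n, n_countries=n_countries)


class TestRubinPooling:
    def test_single_imputation_is_identity(self):
        r = _result(np.array([0.1, -0.2]), np.array([0.05, 0.04]))
        pooled = pool_rubin([r])
        pd.testing.assert_frame_equal(pooled.terms, r.terms)
        assert pooled.m_imputations == 1

    def test_identical_fits_pool_to_within_variance(self):
        r = _result(np.array([0.1]), np.array([0.05]))
        pooled = pool_rubin([r, _result(np.array([0.1]), np.array([0.05]))])
        assert pooled.terms.loc["t0", "se"] == pytest.approx(0.05)

    def test_five_imputations_match_explicit_formula(self):
        rng = np.random.default_rng(17)
        Q = rng.normal(0.1, 0.02, (3, 5))
        U = rng.uniform(0.03, 0.06, (3, 5)) ** 2
        results = [_result(Q[:, j], np.sqrt(U[:, j])) for j in range(5)]
        pooled = pool_rubin(results)
        m = 5
        for i in range(3):
            qbar = Q[i].mean()
            T = U[i].mean() + (1 + 1 / m) * Q[i].var(ddof=1)
            assert pooled.terms["estimate"].iloc[i] == pytest.approx(qbar)
            assert pooled.terms["se"].iloc[i] == pytest.approx(np.sqrt(T))

    def test_mismatched_terms_rejected(self):
        a = _result(np.array([0.1]), np.array([0.05]))
        b = _result(np.array([0.1, 0.2]), np.array([0.05, 0.05]))
        with pytest.raises(ValueError, match="mismatched"):
            pool_rubin([a, b])
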