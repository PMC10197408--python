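"""Post-stratification, design-weighted prevalence, quintiles and quartiles."""

import numpy as np
import pandas as pd
import pytest

from healthineq import (PostStratifier, assign_country_quartiles,
                        assign_income_quintiles, percentage_difference,
                        poststratify_weights, weighted_prevalence)


@pytest.fixture
def two_band_sample():
    """One country, weighted band shares (0.8, 0.2), total weight 100."""
    return pd.DataFrame({
        "country_code": "A",
        "age_band": ["55-59"] * 8 + ["85+"] * 2,
        "sample_weight": 10.0,
    })


REF = pd.Series({"55-59": 0.5, "85+": 0.5})


class TestPostStratification:
    def test_band_factors_and_shares(self, two_band_sample):
        adj = poststratify_weights(two_band_sample, REF)
        factors = np.sort((adj / two_band_sample["sample_weight"]).unique())
        np.testing.assert_allclose(factors, [0.625, 2.5])
        shares = adj.groupby(two_band_sample["age_band"]).sum() / adj.sum()
        np.testing.assert_allclose(shares.sort_index(), [0.5, 0.5], atol=1e-12)
        assert adj.sum() == pytest.approx(100.0)

    def test_fixed_point_when_shares_already_match(self):
        df = pd.DataFrame({"country_code": "A",
                           "age_band": ["55-59", "85+"],
                           "sample_weight": [5.0, 5.0]})
        np.testing.assert_allclose(poststratify_weights(df, REF),
                                   df["sample_weight"])

    def test_idempotence(self, two_band_sample):
        once = poststratify_weights(two_band_sample, REF)
        twice = poststratify_weights(
            two_band_sample.assign(sample_weight=once), REF)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_exactness_within_each_country(self, small_cohort):
        from healthineq import reference_age_structure
        micro, _, _ = small_cohort
        ref = reference_age_structure()
        adj = poststratify_weights(micro, ref)
        for _, sub in micro.assign(w=adj).groupby("country_code"):
            shares = sub.groupby("age_band")["w"].sum() / sub["w"].sum()
            assert (shares.reindex(ref.index).fillna(0) - ref).abs().max() < 1e-9
            assert sub["w"].sum() == pytest.approx(
                micro.loc[sub.index, "sample_weight"].sum())

    def test_unsampled_band_with_positive_share_errors(self, two_band_sample):
        ref3 = pd.Series({"55-59": 0.4, "85+": 0.4, "70-74": 0.2})
        with pytest.raises(ValueError, match="70-74"):
            poststratify_weights(two_band_sample, ref3)

    def test_transformer_wrapper(self, two_band_sample):
        out = PostStratifier().fit(None, ref=REF).transform(two_band_sample)
        np.testing.assert_allclose(
            out["sample_weight"], poststratify_weights(two_band_sample, REF))


class TestWeightedPrevalence:
    @pytest.mark.parametrize("h,w,expected", [
        ([1, 1, 0, 0], [1, 1, 1, 1], 50.0),
        ([1, 0], [3, 1], 75.0),
    ])
    def test_point_estimates(self, h, w, expected):
        assert weighted_prevalence(h, w).prevalence == pytest.approx(expected)

    def test_all_zero_outcome_degenerate_interval(self):
        est = weighted_prevalence([0, 0, 0], [1, 1, 1])
        assert (est.prevalence, est.ci_low, est.ci_high) == (0.0, 0.0, 0.0)

    def test_single_cluster_stratum_warns_and_falls_back(self):
        with pytest.warns(UserWarning, match="single cluster"):
            est = weighted_prevalence([1, 0, 1, 0], [1, 1, 1, 1],
                                      strata=["s"] * 4, clusters=["c"] * 4)
        assert est.prevalence == pytest.approx(50.0)

    def test_interval_ordering_and_bounds(self):
        rng = np.random.default_rng(0)
        est = weighted_prevalence(rng.integers(0, 2, 500),
                                  rng.uniform(0.5, 2, 500),
                                  strata=np.repeat(["a", "b"], 250),
                                  clusters=rng.integers(0, 10, 500))
        assert 0 <= est.ci_low <= est.prevalence <= est.ci_high <= 100

    def test_estimator_unbiased_with_nominal_coverage(self):
        """200 SRS replicates at n=2000, p=0.3: mean estimate within 3 MC
        standard errors of 30% and logit-interval coverage in [92%, 98%]."""
        rng = np.random.default_rng(100)
        n, p, reps = 2000, 0.3, 200
        estimates, covered = [], 0
        for _ in range(reps):
            h = (rng.random(n) < p).astype(float)
            est = weighted_prevalence(h, np.ones(n))
            estimates.append(est.prevalence)
            covered += est.ci_low <= 100 * p <= est.ci_high
        mc_se = 100 * np.sqrt(p * (1 - p) / n) / np.sqrt(reps)
        assert abs(np.mean(estimates) - 30.0) < 3 * mc_se
        assert 0.92 <= covered / reps <= 0.98


class TestIncomeQuintiles:
    def test_uniform_case_exact_twenty_percent(self):
        df = pd.DataFrame({"country_code": "A",
                           "income_pc": np.arange(100.0),
                           "sample_weight": 1.0})
        q = assign_income_quintiles(df)
        assert np.bincount(q)[1:].tolist() == [20] * 5

    def test_dominant_weight_boundary_handling(self):
        """One person holding 80% of the weight sits in the lowest quintile
        whose upper cut point covers their income (here Q2)."""
        df = pd.DataFrame({"country_code": "A",
                           "income_pc": [1.0, 2.0, 3.0, 4.0, 5.0],
                           "sample_weight": [1, 1, 1, 1, 16.0]})
        assert assign_income_quintiles(df).tolist() == [1, 1, 1, 1, 2]

    def test_households_with_tied_income_share_quintile(self):
        df = pd.DataFrame({"country_code": "A",
                           "income_pc": [1, 1, 2, 3, 4, 5, 6, 7.0],
                           "sample_weight": 1.0})
        q = assign_income_quintiles(df)
        assert q.iloc[0] == q.iloc[1]

    def test_quintiles_are_within_country(self):
        df = pd.DataFrame({
            "country_code": ["A"] * 5 + ["B"] * 5,
            "income_pc": [1, 2, 3, 4, 5, 100, 200, 300, 400, 500.0],
            "sample_weight": 1.0})
        q = assign_income_quintiles(df)
        assert q.tolist() == [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]

    def test_weighted_shares_within_boundary_tolerance(self, small_cohort):
        micro, _, _ = small_cohort
        q = assign_income_quintiles(micro)
        for cc, sub in micro.assign(q=q).groupby("country_code"):
            w = sub["sample_weight"]
            shares = w.groupby(sub["q"]).sum() / w.sum()
            # a cut can only overshoot by the weight of the boundary income
            # tie-block (a whole household when incomes tie exactly)
            block_max = w.groupby(sub["income_pc"]).sum().max()
            tol = 2 * block_max / w.sum()
            assert (shares - 0.2).abs().max() <= tol + 1e-12

    def test_degenerate_incomes_rejected(self):
        df = pd.DataFrame({"country_code": "A", "income_pc": [5.0] * 10,
                           "sample_weight": 1.0})
        with pytest.raises(ValueError, match="distinct"):
            assign_income_quintiles(df)


class TestPercentageDifference:
    @pytest.mark.parametrize("q1,q5,expected", [
        (20.0, 10.0, 50.0),
        (23.1, 11.8, 48.917748917748916),
        (10.0, 10.0, 0.0),
    ])
    def test_formula(self, q1, q5, expected):
        assert percentage_difference(q1, q5) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percentage_difference(0.0, 5.0)


class TestCountryQuartiles:
    def test_eight_distinct_values_two_per_quartile(self):
        m = pd.DataFrame({"country_code": list("abcdefgh"),
                          "v": np.arange(8.0)})
        assert assign_country_quartiles(m, "v").tolist() == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_ties_share_lower_quartile(self):
        m = pd.DataFrame({"country_code": list("abcdefgh"),
                          "v": [1, 1, 1, 5, 6, 7, 8, 9.0]})
        q = assign_country_quartiles(m, "v")
        assert q.loc[["a", "b", "c"]].tolist() == [1, 1, 1]

    def test_fewer_than_four_countries_rejected(self):
        m = pd.DataFrame({"country_code": list("abc"), "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            assign_country_quartiles(m, "v")
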