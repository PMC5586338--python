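import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from pollenlag.ordinal import (ClmSpec, CumulativeLinkModel,
                               RankDeficiencyError, build_design, fit_clm,
                               negative_log_likelihood)

from _oracles import brute_force_nll
from conftest import make_design


class TestBuildDesign:
    def test_treatment_coding_column_count(self, small_survey):
        d = build_design(small_survey, ClmSpec(factors=("site",)))
        assert d.X.shape[1] == 1 + (3 - 1)
        assert d.xnames == ["day", "site[BE]", "site[RM]"]
        assert d.levels["site"][0] == "AC"  # alphabetical reference

    def test_unbalanced_interaction_rank_deficient(self, multi_year_survey):
        spec = ClmSpec(factors=("site", "year"), interaction=True)
        with pytest.raises(RankDeficiencyError, match="interaction"):
            build_design(multi_year_survey, spec)

    def test_common_site_subset_makes_interaction_full_rank(self, multi_year_survey):
        sites = multi_year_survey.sites_in_all_years()
        assert sites == ["AC", "BE", "RM"]
        spec = ClmSpec(factors=("site", "year"), interaction=True,
                       subset={"site": sites})
        d = build_design(multi_year_survey, spec)
        # 1 time + 2 site + 2 year + 4 interaction
        assert d.X.shape[1] == 9
        assert np.linalg.matrix_rank(d.X) == 9

    def test_empty_subset_errors(self, small_survey):
        with pytest.raises(ValueError, match="empty"):
            build_design(small_survey, ClmSpec(subset={"year": [1999]}))

    def test_reference_level_override(self, small_survey):
        d = build_design(small_survey, ClmSpec(reference_levels={"site": "BE"}))
        assert d.levels["site"][0] == "BE"
        assert "site[BE]" not in d.xnames


class TestNegativeLogLikelihood:
    def test_symmetric_two_level_single_observation(self):
        d = make_design([0], [[0.0]], 2)
        nll = negative_log_likelihood([0.0], [0.0], d)
        assert nll == pytest.approx(math.log(2), abs=1e-12)

    def test_non_increasing_thresholds_rejected(self):
        d = make_design([0, 1, 2], [[0.0]] * 3, 3)
        with pytest.raises(ValueError, match="increasing"):
            negative_log_likelihood([1.0, 1.0], [0.0], d)

    def test_matches_brute_force_on_handpicked_seven_level_case(self):
        theta = [-2.5, -1.0, 0.0, 0.7, 1.8, 3.0]
        beta = [0.4, -1.1]
        X = [[1.0, 0.0], [2.5, 1.0], [-0.5, 1.0]]
        y = [0, 4, 6]
        d = make_design(y, X, 7)
        ours = negative_log_likelihood(theta, beta, d)
        oracle = brute_force_nll(theta, beta, [1, 5, 7], X,
                                 levels=[1, 2, 3, 4, 5, 6, 7])
        assert ours == pytest.approx(oracle, abs=1e-12)


class TestFit:
    def test_balanced_intercept_only_recovers_logit_quantiles(self):
        df = pd.DataFrame({"score": np.repeat(np.arange(1, 8), 12)})
        res = fit_clm(df, ClmSpec(time_term=None, factors=()))
        expected = logit(np.arange(1, 7) / 7)
        assert np.max(np.abs(res.thresholds - expected)) < 1e-6
        assert res.converged

    def test_two_category_fit_matches_reference_logistic_regression(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(8)
        x = rng.normal(size=400)
        p = 1 / (1 + np.exp(-(0.3 + 0.9 * x)))
        y = (rng.random(400) < p).astype(int)
        df = pd.DataFrame({"score": y + 1, "day": x})
        res = fit_clm(df, ClmSpec(factors=()))
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        # P(Y=2) = F(beta*x - theta1): intercept = -theta1, slope = beta
        assert res.thresholds[0] == pytest.approx(-ref.params[0], abs=1e-6)
        assert res.beta["day"] == pytest.approx(ref.params[1], abs=1e-6)

    def test_full_model_matches_statsmodels_ordered_model(self, small_survey):
        """Seven-level fit with covariates agrees with an independently
        implemented proportional-odds fitter (loglik and coefficients)."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel
        res = fit_clm(small_survey, ClmSpec(factors=("site",)))
        df = small_survey.data
        exog = pd.DataFrame({
            "day": df["day"].astype(float),
            "site[BE]": (df["site"] == "BE").astype(float),
            "site[RM]": (df["site"] == "RM").astype(float),
        })
        ref = OrderedModel(df["score"], exog, distr="logit").fit(
            method="bfgs", disp=0)
        assert res.llf == pytest.approx(ref.llf, abs=1e-4)
        for name in ["day", "site[BE]", "site[RM]"]:
            assert res.beta[name] == pytest.approx(ref.params[name], abs=1e-4)

    def test_translation_equivariance_in_day(self, small_survey):
        res0 = fit_clm(small_survey, ClmSpec())
        shifted = small_survey.data.copy()
        shifted["day"] = shifted["day"] + 10
        res1 = fit_clm(shifted, ClmSpec())
        assert res1.beta["day"] == pytest.approx(res0.beta["day"], abs=1e-6)
        np.testing.assert_allclose(res1.thresholds,
                                   res0.thresholds + 10 * res0.beta["day"],
                                   atol=1e-5)

    def test_loglik_at_mle_beats_generating_parameters(self, small_survey):
        from pollenlag import SimulationParams
        params = SimulationParams(sites=(("AC", 0.0), ("RM", 5.0), ("BE", 12.0)),
                                  years=((2014, 0.0),), n_trees=8, tree_sd=2.0)
        res = fit_clm(small_survey, ClmSpec())
        d = res.design
        theta_true = np.array(params.thresholds)
        # generating model: eta = b*(day + site_eff); treatment-coded betas
        beta_true = np.array([0.30, 0.30 * 12.0, 0.30 * 5.0])
        nll_true = negative_log_likelihood(theta_true, beta_true, d)
        assert -res.llf <= nll_true + 1e-8

    def test_separation_warning_names_level(self):
        df = pd.DataFrame({
            "score": [1, 1, 1, 2, 3, 2, 3, 2],
            "day": [1.0, 2, 3, 1, 2, 3, 1, 2],
            "site": ["Z", "Z", "Z", "A", "A", "A", "A", "A"],
        })
        with pytest.warns(UserWarning, match=r"separation.*site\[Z\]"):
            CumulativeLinkModel(df, ClmSpec(factors=("site",)))

    def test_parameter_recovery_of_day_slope(self):
        """At large n the day slope lands within 3 SE of the generating 0.30.

        tree_sd is 0 so the fitted plain CLM *is* the generating model;
        latent tree heterogeneity would attenuate the slope (it cancels in
        the lag ratio, which is why lags are still recovered with tree
        effects present)."""
        from pollenlag import SimulationParams, simulate_survey
        hits = 0
        for seed in range(10):
            sv = simulate_survey(SimulationParams(
                sites=(("A", 0.0), ("B", 6.0)), years=((2014, 0.0),),
                n_trees=20, tree_sd=0.0, seed=seed))
            res = fit_clm(sv, ClmSpec())
            se = res.bse["day"]
            if abs(res.beta["day"] - 0.30) <= 3 * se:
                hits += 1
        assert hits >= 9


@pytest.fixture(scope="module")
def fitted(small_survey):
    return fit_clm(small_survey, ClmSpec())


class TestPredictions:
    def test_midpoint_probability_half(self, fitted):
        """When eta sits exactly on theta_4, P(score >= 5) = 0.5."""
        eta_needed = fitted.thresholds[3]
        day = (eta_needed - fitted.factor_coef("site", "AC")) / fitted.beta_time
        p = fitted.predict_exceedance(5, day, site="AC")
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_probability_limits_with_positive_slope(self, fitted):
        assert fitted.beta_time > 0
        assert fitted.predict_exceedance(5, 1e4, site="AC") == pytest.approx(1.0)
        assert fitted.predict_exceedance(5, -1e4, site="AC") == pytest.approx(0.0)

    def test_category_masses_sum_to_one(self, fitted):
        probs = fitted.predict_categories(23.0, site="RM")
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (probs >= 0).all()

    def test_unknown_level_rejected(self, fitted):
        with pytest.raises(KeyError, match="unknown"):
            fitted.predict_exceedance(5, 20.0, site="XX")

    def test_cumulative_curves_never_cross_across_stages(self, fitted):
        """Proportional odds: exceedance is ordered in the stage at every
        covariate point."""
        days = np.linspace(-20, 80, 41)
        curves = [fitted.exceedance_curve(s, days, site="BE").to_numpy()
                  for s in range(2, 8)]
        for hi, lo in zip(curves[:-1], curves[1:]):
            assert (hi >= lo - 1e-12).all()

    def test_summary_mentions_key_quantities(self, fitted):
        text = fitted.summary()
        assert "log-likelihood" in text
        assert "site[BE]" in text
        assert "reference site: AC" in text
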