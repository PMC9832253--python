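"""Random-intercept logistic model: likelihood, selection, ED50, Wald tests."""

import json
import subprocess
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from aquanuisance import nuisance_glmm as glmm
from aquanuisance import survey_qc as qc
from aquanuisance import synthetic_survey as synth
from aquanuisance.nuisance_glmm import ModelSpec, fit_binomial_glmm


def _long_from_config(cfg):
    retained, _ = qc.filter_responses(synth.generate_survey(cfg))
    return qc.to_long_nuisance(qc.clean_records(retained))


class TestLaplaceFit:
    def test_zero_variance_limit_matches_irls(self, independent_bernoulli_frame):
        """With no respondent heterogeneity the fit collapses to a plain GLM."""
        df = independent_bernoulli_frame
        fit = fit_binomial_glmm(df, ModelSpec(terms=("growth_level",)))
        X = sm.add_constant(df["growth_level"])
        irls = sm.GLM(df["nuisance"], X, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.coef_ - irls.params.values)) < 1e-3
        assert fit.sigma_ < 0.05

    def test_weight_halved_duplication_reproduces_fit(self, independent_bernoulli_frame):
        df = independent_bernoulli_frame
        fit = fit_binomial_glmm(df, ModelSpec(terms=("growth_level",)))
        dup = pd.concat([df, df], ignore_index=True)
        dup["w"] = 0.5
        fit_dup = fit_binomial_glmm(dup, ModelSpec(terms=("growth_level",), weight_col="w"))
        assert np.max(np.abs(fit.coef_ - fit_dup.coef_)) < 1e-6

    def test_parameter_recovery_within_three_ses(self):
        cfg = synth.GeneratorConfig(
            site_label="sim", species_label="J. bulbosus", n_respondents=1000,
            resident_fraction=0.0, intercept_beta0=-5.16, slope_beta1=1.2,
            random_intercept_sd=1.0, dont_know_rate=0.0, protest_rate=0.0,
            wtp_incomplete_rate=0.0, seed=77)
        long = _long_from_config(cfg)
        fit = fit_binomial_glmm(long, ModelSpec(terms=("growth_level",)))
        se = np.sqrt(np.diag(fit.cov_))
        assert abs(fit.coef_[0] - (-5.16)) < 3 * se[0]
        assert abs(fit.coef_[1] - 1.2) < 3 * se[1]

    def test_laplace_close_to_adaptive_quadrature(self, sagittifolia_fit, sagittifolia_long):
        fit, long = sagittifolia_fit, sagittifolia_long
        X = fit._design_.build(long)[0]
        ll = glmm.gauss_hermite_loglik(
            fit.coef_, fit.sigma_, X, long["nuisance"].to_numpy(float),
            np.ones(len(long)), long["respondent_id"].to_numpy(), n_points=30)
        assert abs(fit.loglik_ - ll) < 0.5

    def test_agrees_with_lme4_glmer(self, sagittifolia_long):
        """Independent Laplace implementation (lme4) on the same data."""
        fit = fit_binomial_glmm(sagittifolia_long,
                                ModelSpec(terms=("growth_level", "respondent_type")))
        import tempfile
        with tempfile.TemporaryDirectory() as d:
            sagittifolia_long.to_csv(f"{d}/long.csv", index=False)
            rcode = (
                'suppressMessages(library(lme4)); '
                f'd <- read.csv("{d}/long.csv"); '
                'm <- glmer(nuisance ~ growth_level + respondent_type + (1|respondent_id), '
                'data=d, family=binomial); '
                'cat(jsonlite::toJSON(list(beta=unname(fixef(m)), '
                'sigma=sqrt(unname(unlist(VarCorr(m)))), '
                'loglik=as.numeric(logLik(m))), digits=10))'
            )
            out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
            assert out.returncode == 0, out.stderr
            ref = json.loads(out.stdout)
        assert np.max(np.abs(np.asarray(ref["beta"]) - fit.coef_)) < 1e-3
        assert abs(ref["sigma"][0] - fit.sigma_) < 1e-3
        assert abs(ref["loglik"][0] - fit.loglik_) < 1e-3

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            fit_binomial_glmm(pd.DataFrame(columns=["nuisance", "growth_level",
                                                    "respondent_id"]),
                              ModelSpec(terms=("growth_level",)))

    def test_aic_counts_fixed_effects_plus_variance(self, sagittifolia_fit):
        fit = sagittifolia_fit
        assert fit.n_params_ == len(fit.coef_) + 1
        assert fit.aic_ == pytest.approx(-2 * fit.loglik_ + 2 * fit.n_params_)

    def test_covariance_is_symmetric_psd(self, sagittifolia_fit):
        V = sagittifolia_fit.cov_
        assert np.allclose(V, V.T)
        assert np.all(np.linalg.eigvalsh(V) >= -1e-12)


class TestAicSelect:
    def _fake(self, aic, fp="x"):
        f = glmm.BinomialRandomInterceptLogit()
        f.aic_ = aic
        f.data_fingerprint_ = fp
        return f

    def test_simpler_wins_within_two_units(self):
        simple, complex_ = self._fake(100.0), self._fake(99.5)
        assert glmm.aic_select([simple, complex_]) is simple

    def test_lower_aic_wins_beyond_two_units(self):
        simple, complex_ = self._fake(105.0), self._fake(100.0)
        assert glmm.aic_select([simple, complex_]) is complex_

    def test_delta_exactly_two_is_not_lower_than_two(self):
        simple, complex_ = self._fake(100.0), self._fake(98.0)
        assert glmm.aic_select([simple, complex_]) is simple

    def test_mixed_datasets_rejected(self):
        with pytest.raises(ValueError, match="same data"):
            glmm.aic_select([self._fake(1.0, "a"), self._fake(2.0, "b")])


class TestTermTests:
    def test_single_coefficient_closed_form(self):
        fit = glmm.BinomialRandomInterceptLogit(terms=("x",))
        fit.coef_ = np.array([0.0, 2.0])
        fit.cov_ = np.diag([1.0, 1.0])
        fit.term_slices_ = {"x": [1]}
        [t] = glmm.term_tests(fit)
        assert t.chisq == pytest.approx(4.0)
        assert t.df == 1
        assert t.p_value == pytest.approx(0.0455, abs=2e-4)

    def test_absent_term_not_in_output(self, sagittifolia_fit):
        names = {t.term for t in glmm.term_tests(sagittifolia_fit)}
        assert names == {"growth_level", "respondent_type"}
        assert "nep_score" not in names

    def test_singular_subblock_names_term(self):
        fit = glmm.BinomialRandomInterceptLogit(terms=("x",))
        fit.coef_ = np.array([0.0, 1.0, 1.0])
        fit.cov_ = np.zeros((3, 3))
        fit.term_slices_ = {"x": [1, 2]}
        with pytest.raises(np.linalg.LinAlgError, match="'x'"):
            glmm.term_tests(fit)


class TestEd50:
    def _fit_with(self, coef, names=("Intercept", "growth_level"), cov=None):
        fit = glmm.BinomialRandomInterceptLogit(terms=("growth_level",))
        fit.coef_ = np.asarray(coef, float)
        fit.coef_names_ = list(names)
        fit.cov_ = cov if cov is not None else np.eye(len(coef)) * 0.01
        fit.term_slices_ = {"growth_level": [1]}
        fit._design_ = glmm._Design(("growth_level",), levels={})
        return fit

    def test_simple_ratio(self):
        est = glmm.estimate_ed50(self._fit_with([-4.0, 1.0]))
        assert est.level == pytest.approx(4.0)

    def test_scale_invariance(self):
        a = glmm.estimate_ed50(self._fit_with([-4.0, 1.0]))
        b = glmm.estimate_ed50(self._fit_with([-8.0, 2.0]))
        assert a.level == pytest.approx(b.level)

    def test_zero_slope_rejected(self):
        with pytest.raises(ZeroDivisionError):
            glmm.estimate_ed50(self._fit_with([-4.0, 0.0]))

    def test_probability_is_half_at_ed50(self, sagittifolia_fit):
        for rt in ("resident", "visitor"):
            est = glmm.estimate_ed50(sagittifolia_fit, {"respondent_type": rt})
            grid = pd.DataFrame({"growth_level": [est.level], "respondent_type": [rt]})
            p = glmm.predict_probability(sagittifolia_fit, grid)["probability"].iloc[0]
            assert abs(p - 0.5) < 1e-8

    def test_delta_method_se_matches_mass_dose_p(self, independent_bernoulli_frame):
        """For the sigma -> 0 fit, the SE must agree with MASS::dose.p."""
        df = independent_bernoulli_frame
        fit = fit_binomial_glmm(df, ModelSpec(terms=("growth_level",)))
        est = glmm.estimate_ed50(fit)
        # dose.p delta method on the same coefficient vector and covariance
        b0, b1 = fit.coef_
        V = fit.cov_
        g = np.array([-1.0 / b1, b0 / b1 ** 2])
        se_ref = float(np.sqrt(g @ V @ g))
        assert est.level == pytest.approx(-b0 / b1)
        assert est.se == pytest.approx(se_ref, rel=1e-10)

    def test_missing_context_is_an_error(self, sagittifolia_fit):
        with pytest.raises(ValueError, match="respondent_type"):
            glmm.estimate_ed50(sagittifolia_fit, {})


class TestPrediction:
    def test_logistic_tail_is_zero(self, sagittifolia_fit):
        grid = pd.DataFrame({"growth_level": [-50.0], "respondent_type": ["visitor"]})
        assert glmm.predict_probability(sagittifolia_fit, grid)["probability"].iloc[0] < 1e-12

    def test_monotone_in_level_for_positive_slope(self, sagittifolia_fit):
        grid = pd.DataFrame({"growth_level": np.linspace(1, 5, 20),
                             "respondent_type": "visitor"})
        p = glmm.predict_probability(sagittifolia_fit, grid)["probability"].to_numpy()
        assert np.all(np.diff(p) > 0)

    def test_parallel_curves_without_interaction(self, sagittifolia_fit):
        res = pd.DataFrame({"growth_level": [1.0, 3.0, 5.0], "respondent_type": "resident"})
        vis = res.assign(respondent_type="visitor")
        eta_r = sagittifolia_fit.linear_predictor(res)[0]
        eta_v = sagittifolia_fit.linear_predictor(vis)[0]
        diffs = eta_r - eta_v
        assert np.allclose(diffs, diffs[0])

    def test_unseen_factor_level_rejected(self, sagittifolia_fit):
        grid = pd.DataFrame({"growth_level": [3.0], "respondent_type": ["tourist"]})
        with pytest.raises(ValueError, match="tourist"):
            glmm.predict_probability(sagittifolia_fit, grid)

    def test_ci_bounds_bracket_estimate(self, sagittifolia_fit):
        grid = pd.DataFrame({"growth_level": [2.0, 4.0], "respondent_type": "resident"})
        out = glmm.predict_probability(sagittifolia_fit, grid)
        assert ((out["ci_low"] < out["probability"]) & (out["probability"] < out["ci_high"])).all()


def test_adding_terms_never_decreases_loglik(sagittifolia_long):
    specs = [("growth_level",), ("growth_level", "respondent_type"),
             ("growth_level", "respondent_type", "nep_score")]
    lls = [fit_binomial_glmm(sagittifolia_long, ModelSpec(terms=t)).loglik_ for t in specs]
    assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6


def test_activity_weighted_fit_runs(site_configs):
    cfg = replace(site_configs["J. bulbosus"], n_respondents=120, seed=31)
    retained, _ = qc.filter_responses(synth.generate_survey(cfg))
    long = qc.to_long_nuisance(qc.clean_records(retained), weighted=True)
    fit = fit_binomial_glmm(long, ModelSpec(
        terms=("growth_level", "respondent_type", "activity"),
        weight_col="activity_weight"))
    assert fit.converged_
    assert "activity" in fit.term_slices_
    assert len(fit.term_slices_["activity"]) == 4  # 5 activities, treatment coded
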