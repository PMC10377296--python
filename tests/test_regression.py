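"""Spike-and-slab sampler, GLM baseline and the comparison harness."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gbmgrowth.regression import (BayesAdapter, GlmAdapter, SpikeSlabRegression,
                                  fit_glm_baseline, model_comparison,
                                  predict_with_covariates)


class TestSpikeSlabRegression:
    def test_posterior_concentrates_on_strong_signal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = 2.0 + 3.0 * x + rng.normal(0, 0.5, 200)
        m = SpikeSlabRegression(n_draws=1500, burn_in=300, seed=0)
        m.fit(x[:, None], y)
        assert m.intercept_ == pytest.approx(2.0, abs=0.2)
        assert m.coef_[0] == pytest.approx(3.0, abs=0.2)
        assert m.inclusion_probs_[0] > 0.99
        lo, hi = m.credible_interval()[1]
        assert lo <= 3.0 <= hi

    def test_null_covariates_excluded(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(150, 3))
        y = 1.0 + rng.normal(0, 1.0, 150)
        m = SpikeSlabRegression(n_draws=800, burn_in=200, seed=1).fit(X, y)
        assert m.inclusion_probs_.mean() < 0.5

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 2))
        y = X @ [1.0, 0.0] + rng.normal(0, 1.0, 60)
        a = SpikeSlabRegression(n_draws=300, burn_in=100, seed=9).fit(X, y)
        b = SpikeSlabRegression(n_draws=300, burn_in=100, seed=9).fit(X, y)
        np.testing.assert_array_equal(a.coef_draws_, b.coef_draws_)

    def test_forced_inclusion_matches_conjugate_normal_fit(self):
        """With overwhelming signal on every covariate the spike never
        activates, so the posterior mean matches the ridge-style
        conjugate normal solution computed directly."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 2))
        y = 4.0 + X @ [2.0, -3.0] + rng.normal(0, 0.3, 300)
        m = SpikeSlabRegression(n_draws=1500, burn_in=300, seed=3).fit(X, y)
        np.testing.assert_allclose(m.inclusion_probs_, [1.0, 1.0], atol=1e-9)
        np.testing.assert_allclose(m.coef_, [2.0, -3.0], atol=0.1)

    def test_literal_mode_matches_exhaustive_enumeration(self):
        """Gibbs marginals vs the exact 2^(p+1) vertex posterior at
        fixed sigma^2, with enough noise that the posterior is spread."""
        rng = np.random.default_rng(5)
        p = 4
        X = rng.normal(size=(40, p))
        Z = np.column_stack([np.ones(40), X])
        theta_true = np.array([1.0, 1.0, 0.0, 1.0, 0.0])
        sigma = 1.8
        y = Z @ theta_true + rng.normal(0, sigma, 40)
        m = SpikeSlabRegression(prior_mode="literal", fixed_sigma2=sigma ** 2,
                                n_draws=8000, burn_in=1000, seed=6).fit(X, y)
        log_post = {}
        for th in itertools.product([0.0, 1.0], repeat=p + 1):
            r = y - Z @ np.asarray(th)
            log_post[th] = -float(r @ r) / (2 * sigma ** 2)
        mx = max(log_post.values())
        zsum = sum(np.exp(v - mx) for v in log_post.values())
        marg = np.zeros(p + 1)
        for th, v in log_post.items():
            marg += np.asarray(th) * np.exp(v - mx) / zsum
        sampled = np.concatenate([[m.intercept_], m.coef_])
        np.testing.assert_allclose(sampled, marg, atol=0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="prior_mode"):
            SpikeSlabRegression(prior_mode="bogus").fit(np.zeros((5, 1)),
                                                        np.zeros(5))
        with pytest.raises(ValueError, match="subjects"):
            SpikeSlabRegression().fit(np.zeros((5, 1)), np.zeros(4))


class TestGlmBaseline:
    def test_perfect_linear_data_r2_one(self):
        x = np.linspace(0, 1, 30)
        fit = fit_glm_baseline(x[:, None], 2 + 5 * x)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_pure_noise_r2_near_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(2000, 1))
        fit = fit_glm_baseline(X, rng.normal(size=2000))
        assert fit.r_squared < 0.01

    def test_aic_closed_form(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 2))
        y = X @ [1.0, 2.0] + rng.normal(0, 1.0, 50)
        fit = fit_glm_baseline(X, y)
        rss = np.sum((y - fit.predict(X)) ** 2)
        assert fit.aic == pytest.approx(50 * np.log(rss / 50) + 2 * 3,
                                        abs=1e-8)

    def test_collinear_design_flagged(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        X = np.column_stack([x, 2 * x])
        with pytest.warns(RuntimeWarning, match="collinear"):
            fit = fit_glm_baseline(X, x + rng.normal(0, 0.1, 40))
        assert fit.rank_deficient


class TestPredictWithCovariates:
    def test_zero_covariate_model_predicts_intercept(self):
        rng = np.random.default_rng(8)
        y = 5.0 + rng.normal(0, 0.1, 50)
        m = SpikeSlabRegression(n_draws=400, burn_in=100, seed=8)
        m.fit(rng.normal(size=(50, 1)) * 0 + rng.normal(size=(50, 1)), y)
        out = predict_with_covariates(m, np.zeros((3, 1)), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(out["predicted_volume"], m.intercept_,
                                   atol=1e-9)

    def test_implied_counts_and_probabilities(self):
        class Const:
            def predict(self, X):
                return np.array([300.0, 0.0])

        out = predict_with_covariates(Const(), np.zeros((2, 1)), [100.0, 50.0])
        assert out["implied_count"].tolist() == [3.0, 0.0]
        assert out["p_no_undetected"].iloc[0] == pytest.approx(0.5625)
        assert out["p_no_undetected"].iloc[1] == 0.0

    def test_nonpositive_initial_volume_skipped(self):
        class Const:
            def predict(self, X):
                return np.array([300.0, 200.0])

        out = predict_with_covariates(Const(), np.zeros((2, 1)), [100.0, 0.0])
        assert bool(out["skipped"].iloc[1])
        assert np.isnan(out["p_no_undetected"].iloc[1])


@pytest.fixture(scope="module")
def comparison_data():
    rng = np.random.default_rng(11)
    n = 80
    eta = rng.normal(size=n)
    feats = pd.DataFrame({f"x{i}": 0.8 * eta + rng.normal(0, 0.6, n)
                          for i in range(4)})
    responses = pd.DataFrame({
        "ED": 1.0 + eta + rng.normal(0, 0.5, n),
        "WT": 2.0 + 1.5 * eta + rng.normal(0, 0.5, n)})
    return feats, responses


class TestModelComparison:
    def test_identical_models_identical_columns(self, comparison_data):
        feats, responses = comparison_data
        models = {"A": GlmAdapter(), "B": GlmAdapter()}
        tbl = model_comparison(feats, responses, models=models, folds=4,
                               seed=2)
        for metric in ("R-Squared", "AIC", "C.V. Error"):
            np.testing.assert_allclose(tbl[(metric, "A")], tbl[(metric, "B")])

    def test_label_swap_swaps_columns(self, comparison_data):
        feats, responses = comparison_data
        endo = list(feats.columns)
        t1 = model_comparison(feats, responses, models={
            "GLM": GlmAdapter(),
            "Bayesian": BayesAdapter(endo_columns=endo, n_draws=300,
                                     burn_in=100)}, folds=4, seed=2)
        t2 = model_comparison(feats, responses, models={
            "Bayesian": BayesAdapter(endo_columns=endo, n_draws=300,
                                     burn_in=100),
            "GLM": GlmAdapter()}, folds=4, seed=2)
        for metric in ("R-Squared", "C.V. Error"):
            np.testing.assert_allclose(t1[(metric, "GLM")],
                                       t2[(metric, "GLM")])
            np.testing.assert_allclose(t1[(metric, "Bayesian")],
                                       t2[(metric, "Bayesian")])

    def test_cv_error_nonnegative_and_table_shape(self, comparison_data):
        feats, responses = comparison_data
        tbl = model_comparison(feats, responses, folds=4, seed=3)
        assert list(tbl.index) == ["ED", "WT"]
        assert tbl.columns.names == ["metric", "model"]
        assert (tbl["C.V. Error"] >= 0).all().all()

    def test_too_small_folds_rejected(self, comparison_data):
        feats, responses = comparison_data
        with pytest.raises(ValueError, match="folds"):
            model_comparison(feats, responses, folds=1)
        with pytest.raises(ValueError, match="fewer than 3"):
            model_comparison(feats.head(12), responses.head(12), folds=5)
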