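import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from msatbot import abc as abce
from msatbot.abc import (ABCLocalLinearRegressor, ABCModelClassifier,
                         ReferenceTable, _n_accept, abc_reject,
                         build_reference_table, cv_model_choice,
                         cv_param_error, goodness_of_fit, model_posterior,
                         param_posterior, point_estimates,
                         posterior_predictive)
from msatbot.coalsim import BOTTLENECK, NON_BOTTLENECK, PriorSet
from msatbot.sumstats import STAT_NAMES, SummaryVector


class TestBuildReferenceTable:
    def test_row_counts_and_balance(self):
        t = build_reference_table(n_per_model=100,
                                  rng=np.random.default_rng(1))
        assert t.n_rows == 200
        assert t.model_counts() == {BOTTLENECK: 100, NON_BOTTLENECK: 100}

    def test_fixed_seed_bit_identical(self):
        a = build_reference_table(n_per_model=200,
                                  rng=np.random.default_rng(3))
        b = build_reference_table(n_per_model=200,
                                  rng=np.random.default_rng(3))
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_ne_bot_marginal_passes_through(self, small_table):
        x = small_table.df.loc[
            small_table.df["model"] == BOTTLENECK, "ne_bot"]
        ks = sps.kstest(x, sps.uniform(loc=1, scale=499).cdf)
        assert ks.pvalue > 0.01

    def test_save_load_round_trip(self, small_table, tmp_path):
        path = tmp_path / "tab.csv"
        small_table.save(path)
        back = ReferenceTable.load(path)
        pd.testing.assert_frame_equal(back.df, small_table.df)
        assert back.priors == small_table.priors
        assert (back.n_ind, back.n_loci) == (40, 10)


class TestRejection:
    def test_acceptance_count_is_ceiling(self, small_table):
        obs = small_table.stats()[0]
        for tol in (5e-4, 0.01, 0.25, 1.0):
            r = abc_reject(obs, small_table, tol)
            assert r.n_accepted == math.ceil(tol * small_table.n_rows)
        # full-scale arithmetic: 5e-4 of 1e7 rows -> 5000 accepted
        assert _n_accept(5e-4, 10**7) == 5000

    def test_observed_row_accepted_at_distance_zero(self, small_table):
        obs = small_table.stats()[123]
        r = abc_reject(obs, small_table, 0.01)
        assert r.indices[0] == 123
        assert r.distances[0] == 0.0

    def test_tolerance_one_accepts_all(self, small_table):
        r = abc_reject(small_table.stats()[0], small_table, 1.0)
        assert r.n_accepted == small_table.n_rows

    def test_monotone_in_tolerance(self, small_table):
        obs = small_table.stats()[7]
        prev = set()
        for tol in (0.001, 0.01, 0.1):
            idx = set(abc_reject(obs, small_table, tol).indices.tolist())
            assert prev <= idx
            prev = idx

    def test_zero_mad_statistic_dropped_with_warning(self, small_table):
        df = small_table.df.copy()
        df["lfa"] = 0.3
        t = ReferenceTable(df, 40, 10, small_table.priors)
        with pytest.warns(UserWarning, match="zero MAD"):
            r = abc_reject(t.stats()[0], t, 0.01)
        assert "lfa" in r.dropped_stats


class TestModelChoice:
    def test_identical_models_give_half(self, rng):
        X = rng.normal(size=(4000, 5))
        y = np.array([BOTTLENECK, NON_BOTTLENECK] * 2000)
        clf = ABCModelClassifier(tolerance=0.05).fit(X, y)
        probs = clf.predict_proba(rng.normal(size=(20, 5)))
        assert probs.sum(axis=1) == pytest.approx(np.ones(20))
        assert abs(probs[:, 0].mean() - 0.5) < 0.1

    def test_disjoint_models_certain(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(500, 5)),
                       rng.normal(8, 0.1, size=(500, 5))])
        y = np.array([BOTTLENECK] * 500 + [NON_BOTTLENECK] * 500)
        clf = ABCModelClassifier(tolerance=0.1).fit(X, y)
        p = clf.predict_proba(np.zeros((1, 5)))[0]
        assert p[list(clf.classes_).index(BOTTLENECK)] > 0.99
        assert clf.predict(np.full((1, 5), 8.0))[0] == NON_BOTTLENECK

    def test_rejection_probs_equal_label_proportions(self, small_table):
        obs = small_table.stats()[4]
        choice = model_posterior(obs, small_table, tolerance=0.05,
                                 method="rejection")
        r = abc_reject(obs, small_table, 0.05)
        labels = small_table.labels()[r.indices]
        for m, p in choice.probs.items():
            assert p == pytest.approx(np.mean(labels == m))
        assert sum(choice.probs.values()) == pytest.approx(1.0)

    def test_deep_bottleneck_recognised(self, small_table, rng):
        # pseudo-observations from a severe bottleneck should mostly be
        # assigned to the bottleneck model
        from msatbot.coalsim import DemographicParams, simulate_dataset
        from msatbot.sumstats import mean_sumstats
        p = DemographicParams(BOTTLENECK, ne=30_000, ne_hist=30_000,
                              mu=5e-5, gsm_par=0.1, ne_bot=20,
                              t_bot_start=60, t_bot_end=5)
        hits = 0
        for _ in range(20):
            ds = simulate_dataset(p, 40, 10, rng)
            c = model_posterior(mean_sumstats(ds), small_table,
                                tolerance=0.025)
            hits += c.p_bot > 0.5
        assert hits >= 16

    def test_sklearn_get_set_params(self):
        clf = ABCModelClassifier(tolerance=0.01)
        assert clf.get_params()["tolerance"] == 0.01
        clf.set_params(method="rejection")
        assert clf.method == "rejection"


class TestLocalLinear:
    def test_linear_toy_recovers_conditional_expectation(self, rng):
        # s = theta + e, theta ~ U(0,1), e ~ N(0, 0.05^2): the analytic
        # posterior mean E[theta | s] comes from numeric integration
        n = 20_000
        theta = rng.uniform(0, 1, n)
        s = theta + rng.normal(0, 0.05, n)
        X = np.column_stack([s, *[rng.normal(size=n) for _ in range(4)]])
        reg = ABCLocalLinearRegressor(tolerance=0.02)
        reg.fit(X, pd.DataFrame({"theta": theta}))
        s_obs = 0.31
        post = reg.posterior(np.array([s_obs, 0, 0, 0, 0]))
        est = np.average(post.adjusted["theta"], weights=post.weights)
        grid = np.linspace(0, 1, 2001)
        dens = sps.norm.pdf(s_obs, loc=grid, scale=0.05)
        analytic = np.trapezoid(grid * dens, grid) / np.trapezoid(dens, grid)
        assert est == pytest.approx(analytic, abs=0.01)

    def test_constant_statistics_leave_draws_unchanged(self, rng):
        n = 2000
        theta = rng.uniform(0, 1, n)
        X = rng.normal(size=(n, 5))
        reg = ABCLocalLinearRegressor(tolerance=0.1, min_accepted=10)
        reg.fit(X, pd.DataFrame({"theta": theta}))
        obs = X[5]
        post = reg.posterior(obs)
        # regression on pure-noise stats: adjustment stays near identity
        assert np.corrcoef(post.raw["theta"],
                           post.adjusted["theta"])[0, 1] > 0.95

    def test_adjusted_ne_bot_respects_prior_support(self, small_table):
        obs = SummaryVector(small_table.stats()[3])
        post = param_posterior(obs, small_table, BOTTLENECK,
                               tolerance=0.05)
        x = post.adjusted["ne_bot"]
        assert (x >= 1).all() and (x <= 500).all()
        assert (post.adjusted["gsm_par"] >= 0).all()
        assert (post.adjusted["gsm_par"] <= 0.3).all()

    def test_min_accepted_enforced(self, small_table):
        with pytest.raises(ValueError, match="accepted"):
            param_posterior(small_table.stats()[0], small_table,
                            BOTTLENECK, tolerance=1e-4)


class TestPointEstimates:
    def _sample(self, draws, weights=None):
        from msatbot.abc import PosteriorSample
        df = pd.DataFrame({"x": draws})
        w = np.ones(len(draws)) if weights is None else weights
        return PosteriorSample(df, df.copy(), w, "m", np.zeros(len(draws)))

    def test_symmetric_sample_mode_near_median(self, rng):
        pe = point_estimates(self._sample(rng.normal(10, 2, 4000)))
        row = pe.loc["x"]
        assert abs(row["mode"] - row["median"]) < 0.5
        assert row["ci_low"] <= row["median"] <= row["ci_high"]

    def test_bimodal_taller_mode_selected(self, rng):
        draws = np.concatenate([rng.normal(0, 0.5, 3000),
                                rng.normal(6, 0.5, 1000)])
        pe = point_estimates(self._sample(draws))
        assert abs(pe.loc["x", "mode"] - 0) < 1.0

    def test_constant_sample_mode_is_constant(self):
        pe = point_estimates(self._sample(np.full(200, 3.3)))
        assert pe.loc["x", "mode"] == pytest.approx(3.3)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            point_estimates(self._sample(np.arange(50.0)))


class TestCrossValidation:
    def test_identical_models_cv_near_half(self, rng):
        X = rng.normal(size=(3000, 5))
        df = pd.DataFrame(X, columns=list(STAT_NAMES))
        df.insert(0, "model", [BOTTLENECK, NON_BOTTLENECK] * 1500)
        for p in abce.PARAM_NAMES:
            df[p] = rng.uniform(size=3000)
        t = ReferenceTable(df, 40, 10, PriorSet())
        cv = cv_model_choice(t, n_reps=40, tolerance=0.05, rng=rng)
        diag = np.diag(cv.model_probs.to_numpy())
        assert np.allclose(diag, 0.5, atol=0.12)

    def test_disjoint_toy_models_cv_near_one(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (1000, 5)),
                       rng.normal(5, 0.1, (1000, 5))])
        df = pd.DataFrame(X, columns=list(STAT_NAMES))
        df.insert(0, "model", [BOTTLENECK] * 1000 + [NON_BOTTLENECK] * 1000)
        for p in abce.PARAM_NAMES:
            df[p] = rng.uniform(size=2000)
        t = ReferenceTable(df, 40, 10, PriorSet())
        cv = cv_model_choice(t, n_reps=30, tolerance=0.02, rng=rng)
        assert np.diag(cv.model_probs.to_numpy()).min() > 0.95

    def test_param_error_perfect_oracle_is_zero(self):
        # if the accepted neighbourhood always contains near-identical
        # parameter values, the prediction error vanishes
        n = 400
        rng = np.random.default_rng(0)
        theta = np.repeat(np.linspace(0, 1, 80), 5)
        X = np.column_stack([theta, theta, theta, theta, theta])
        X = X + rng.normal(0, 1e-9, X.shape)
        df = pd.DataFrame(X, columns=list(STAT_NAMES))
        df.insert(0, "model", BOTTLENECK)
        for p in abce.PARAM_NAMES:
            df[p] = theta
        t = ReferenceTable(df, 40, 10, PriorSet())
        cv = cv_param_error(t, BOTTLENECK, n_reps=50, tolerance=0.01,
                            rng=rng)
        assert (cv.prediction_error < 0.05).all()

    def test_prior_mean_estimator_error_near_one(self, rng):
        # uninformative statistics: the rejection posterior is the prior,
        # whose median ~ prior mean -> normalised error ~ 1
        n = 4000
        df = pd.DataFrame(rng.normal(size=(n, 5)), columns=list(STAT_NAMES))
        df.insert(0, "model", BOTTLENECK)
        for p in abce.PARAM_NAMES:
            df[p] = rng.uniform(size=n)
        t = ReferenceTable(df, 40, 10, PriorSet())
        cv = cv_param_error(t, BOTTLENECK, n_reps=100, tolerance=0.2,
                            rng=rng)
        assert np.allclose(cv.prediction_error, 1.0, atol=0.35)


class TestGoodnessOfFit:
    def test_self_drawn_obs_calibrated(self, small_table, rng):
        # p-values for observations drawn from the model itself should be
        # roughly uniform: the alpha=0.05 rejection rate stays near 5%
        sub = small_table.df[small_table.df["model"] == BOTTLENECK]
        picks = rng.choice(len(sub), 100, replace=False)
        ps = [goodness_of_fit(sub[list(STAT_NAMES)].iloc[i].to_numpy(),
                              small_table, BOTTLENECK, n_null=150,
                              tolerance=0.05, rng=rng).p_value
              for i in picks]
        rej = np.mean(np.array(ps) < 0.05)
        assert rej < 0.15

    def test_outlandish_obs_rejected(self, small_table, rng):
        obs = np.array([2.0, 0.0, 0.99, 1.0, 1.0])
        g = goodness_of_fit(obs, small_table, NON_BOTTLENECK, n_null=200,
                            tolerance=0.05, rng=rng)
        assert g.p_value < 0.05


class TestPosteriorPredictive:
    def test_row_count_and_finite(self, small_table, rng):
        obs = SummaryVector(small_table.stats()[10])
        post = param_posterior(obs, small_table, BOTTLENECK, tolerance=0.1)
        sims = posterior_predictive(post, BOTTLENECK, n_draws=50,
                                    rng=rng)
        assert sims.shape == (50, 5)
        assert np.isfinite(sims.to_numpy()).all()

    def test_well_fitting_obs_within_central_interval(self, small_table):
        rng = np.random.default_rng(14)
        sub = small_table.df[small_table.df["model"] == NON_BOTTLENECK]
        obs = SummaryVector(sub[list(STAT_NAMES)].iloc[17].to_numpy())
        post = param_posterior(obs, small_table, NON_BOTTLENECK,
                               tolerance=0.1)
        sims = posterior_predictive(post, NON_BOTTLENECK, n_draws=400,
                                    rng=rng)
        inside = [
            sims[s].quantile(0.025) <= obs[s] <= sims[s].quantile(0.975)
            for s in STAT_NAMES
        ]
        assert sum(inside) >= 4
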