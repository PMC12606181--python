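import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dyadseq as dq
from dyadseq.mmodel import ModelError, PriorConfig
from dyadseq.simulate import model_cohort


def _classifications(rows):
    return pd.DataFrame(rows, columns=[
        "member_low", "member_high", "familiarity", "sex_composition", "generalized", "precise"
    ])


class TestBuildModelData:
    def test_not_evaluable_dyads_dropped(self):
        rows = [("A", "B", "familiar", "MF", "supported", "supported"),
                ("A", "C", "stranger", "MM", "violated", "violated"),
                ("B", "C", "stranger", "MF", "supported", "violated")]
        rows += [("A", f"X{i}", "stranger", "MM", "not_evaluable", "not_evaluable")
                 for i in range(3)]
        rows += [("B", f"X{i}", "stranger", "MM", "supported", "supported")
                 for i in range(4)]
        data = dq.build_model_data(_classifications(rows), "generalized")
        assert data.n_dyads == 7  # 10 dyads, 3 not evaluable

    def test_missing_familiar_stratum_is_model_error(self):
        rows = [("A", "B", "stranger", "MF", "supported", "supported"),
                ("A", "C", "stranger", "MM", "violated", "violated")]
        with pytest.raises(ModelError, match="familiar"):
            dq.build_model_data(_classifications(rows), "generalized")

    def test_design_columns_match_hand_coding(self):
        rows = [("A", "B", "familiar", "MF", "supported", "violated"),
                ("A", "C", "stranger", "MM", "violated", "violated"),
                ("B", "C", "stranger", "FF", "supported", "supported")]
        data = dq.build_model_data(_classifications(rows), "generalized", include_sex=True)
        assert data.y.tolist() == [1.0, 0.0, 1.0]
        assert data.stranger.tolist() == [0.0, 1.0, 1.0]
        assert data.bird_ids == ["A", "B", "C"]
        assert data.i_idx.tolist() == [0, 0, 1]
        assert data.j_idx.tolist() == [1, 2, 2]
        assert data.sex_mm.tolist() == [0.0, 1.0, 0.0]
        assert data.sex_ff.tolist() == [0.0, 0.0, 1.0]


class TestSummarize:
    def test_degenerate_posterior_odds_factor(self):
        draws = {"beta_stranger": np.full((2, 100), 1.22)}
        s = dq.summarize(draws).set_index("parameter")
        assert round(float(s.loc["beta_stranger", "odds_factor"]), 2) == 3.39

    def test_zero_draws_give_unit_odds(self):
        draws = {"beta_stranger": np.zeros((2, 50))}
        s = dq.summarize(draws).set_index("parameter")
        assert float(s.loc["beta_stranger", "odds_factor"]) == 1.0

    def test_two_point_posterior_odds_mean(self):
        draws = {"beta_stranger": np.array([[0.0, np.log(4.0)]])}
        s = dq.summarize(draws).set_index("parameter")
        assert float(s.loc["beta_stranger", "odds_factor"]) == pytest.approx(2.5)

    def test_odds_factor_is_samplewise_not_exp_of_mean(self):
        """On a right-skewed posterior mean(exp(x)) exceeds exp(mean(x))."""
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 1.0, size=(4, 5000))
        s = dq.summarize({"beta_stranger": x}).set_index("parameter")
        of = float(s.loc["beta_stranger", "odds_factor"])
        assert of == pytest.approx(float(np.mean(np.exp(x))))
        assert of > np.exp(x.mean()) * 1.2  # clearly not exp-of-mean


_FAST = dict(chains=2, total_iter=800, warmup=400, seed=11, thin=2)


class TestFit:
    def test_same_seed_identical_posterior(self):
        rng = np.random.default_rng(3)
        data, _ = model_cohort(rng, site_sizes=(3, 3, 3))
        a = dq.fit(data, **_FAST)
        b = dq.fit(data, **_FAST)
        for k in a.draws:
            assert np.array_equal(a.draws[k], b.draws[k])

    def test_member_order_swap_leaves_familiarity_effect_unchanged(self):
        rng = np.random.default_rng(4)
        data, _ = model_cohort(rng, site_sizes=(4, 4))
        swapped = dq.ModelData(
            data.y, data.stranger, data.j_idx.copy(), data.i_idx.copy(), data.bird_ids
        )
        a = dq.fit(data, **_FAST)
        b = dq.fit(swapped, **_FAST)
        ma, mb = a.flat("beta_stranger").mean(), b.flat("beta_stranger").mean()
        mcse = a.flat("beta_stranger").std() / 20  # generous Monte-Carlo error scale
        assert abs(ma - mb) < 6 * mcse

    def test_posterior_mode_matches_plain_logistic_when_no_heterogeneity(self):
        """With u = 0 in truth, posterior beta ~ the statsmodels GLM estimate."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        data, _ = model_cohort(rng, beta_stranger=1.2, sigma_u=0.0,
                               u=np.zeros(22))
        X = sm.add_constant(data.stranger)
        mle = sm.GLM(data.y, X, family=sm.families.Binomial()).fit()
        fit = dq.fit(data, chains=2, total_iter=1200, warmup=600, seed=6, thin=2)
        beta = fit.flat("beta_stranger")
        # the random effects only widen the posterior; the center must agree
        assert abs(beta.mean() - mle.params[1]) < 2.5 * mle.bse[1]

    def test_diagnostics_report_every_parameter(self):
        rng = np.random.default_rng(7)
        data, _ = model_cohort(rng, site_sizes=(3, 3))
        fit = dq.fit(data, **_FAST)
        diag = fit.diagnostics()
        assert set(diag["parameter"]) == set(data.param_names())
        assert diag["rhat"].notna().all()
        assert (diag["ess"] > 0).all()


def test_simulation_based_calibration_ranks_uniform():
    """Prior-draw recovery: rank of the true familiarity effect among posterior
    draws is uniform over replicates (chi-square GOF, alpha = 0.01)."""
    prior = PriorConfig(fixed_sd=1.5, sigma_df=3, sigma_scale=1.0)
    n_rep, n_bins = 64, 8
    L = 31  # thinned posterior draws per replicate -> ranks 0..31
    ranks = []
    rng = np.random.default_rng(123)
    for r in range(n_rep):
        beta = rng.normal(0, prior.fixed_sd)
        alpha = rng.normal(0, prior.fixed_sd)
        sigma = abs(stats.t.rvs(df=prior.sigma_df, scale=prior.sigma_scale,
                                random_state=rng))
        data, _ = model_cohort(rng, site_sizes=(3, 3, 3), beta_stranger=beta,
                               intercept=alpha, sigma_u=sigma)
        fit = dq.fit(data, chains=2, total_iter=700, warmup=350, seed=9000 + r,
                     priors=prior, thin=1)
        draws = fit.flat("beta_stranger")
        sub = draws[:: max(1, len(draws) // L)][:L]
        ranks.append(int(np.sum(sub < beta)))
    edges = np.linspace(0, L + 1, n_bins + 1)
    counts, _ = np.histogram(ranks, bins=edges)
    chi2 = ((counts - n_rep / n_bins) ** 2 / (n_rep / n_bins)).sum()
    p = stats.chi2.sf(chi2, df=n_bins - 1)
    assert p > 0.01, (counts.tolist(), p)
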