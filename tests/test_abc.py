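"""Priors, rejection, likelihoods and posterior summaries of the ABC layer."""

import numpy as np
import pandas as pd
import pytest

from wolfdemes.abc import (
    abc_distance,
    all_scenarios,
    posterior_summary,
    reject,
    run_abc,
    sample_prior,
    scenario_likelihood,
)
from wolfdemes.sumstats import SUMMARY_STATS

from conftest import make_samples


class TestSamplePrior:
    def test_sixteen_scenarios(self, graph):
        scens = all_scenarios(graph)
        assert len(scens) == 16
        assert scens.count(("static", None)) == 1
        assert sum(1 for f, o in scens if f == "expansion_bottleneck") == 7

    def test_log_uniform_K_median_near_one(self):
        d = sample_prior("static", None, 20_000, seed=0)
        # geometric mean of [0.01, 100] is 1
        assert np.median(d["K"]) == pytest.approx(1.0, rel=0.15)
        assert d["K"].between(0.01, 100).all()
        assert d["m"].between(0.001, 20).all()
        # log10 draws look uniform: compare quartiles
        lk = np.log10(d["K"])
        assert np.percentile(lk, 25) == pytest.approx(-1.0, abs=0.1)
        assert np.percentile(lk, 75) == pytest.approx(1.0, abs=0.1)

    def test_american_origin_T_restricted(self):
        for origin in ("NorthAmerica", "ArcticNorthAmerica"):
            d = sample_prior("expansion", origin, 2000, seed=1)
            assert d["T"].between(9, 16).all()
        d = sample_prior("expansion", "Beringia", 2000, seed=1)
        assert d["T"].between(5, 40).all()
        assert (d["T"] > 16).any()

    def test_bottleneck_has_three_K_columns(self):
        d = sample_prior("expansion_bottleneck", "Europe", 50, seed=2)
        assert {"m", "K1", "K2", "K3", "x", "T", "dT"} == set(d.columns)

    def test_zero_draws_rejected(self):
        with pytest.raises(ValueError):
            sample_prior("static", None, 0, seed=0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            sample_prior("nosuch", None, 10, seed=0)

    def test_reproducible(self):
        d1 = sample_prior("expansion", "Europe", 100, seed=7)
        d2 = sample_prior("expansion", "Europe", 100, seed=7)
        pd.testing.assert_frame_equal(d1, d2)


class TestDistance:
    def test_identical_vectors(self):
        v = pd.Series({s: float(i) for i, s in enumerate(SUMMARY_STATS)})
        assert abc_distance(v, v) == 0.0

    def test_unit_difference_in_each_entry(self):
        v = pd.Series({s: 0.0 for s in SUMMARY_STATS})
        w = v + 1.0
        assert abc_distance(w, v) == pytest.approx(9.0)

    def test_masking_within_me_ignores_that_entry(self):
        names = list(SUMMARY_STATS) + ["ME-ME"]
        v = pd.Series(0.0, index=names)
        w = v.copy()
        w["ME-ME"] = 100.0  # huge discrepancy in the dropped statistic
        assert abc_distance(w, v, stats=SUMMARY_STATS) == 0.0
        assert abc_distance(w, v, stats=names) == pytest.approx(10_000.0)

    def test_missing_observed_entry_rejected(self):
        v = pd.Series(0.0, index=list(SUMMARY_STATS))
        v["EUR-EUR"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            abc_distance(v.copy(), v)

    def test_missing_simulated_entry_is_infinite(self):
        obs = pd.Series(0.0, index=list(SUMMARY_STATS))
        sim = pd.DataFrame([obs, obs])
        sim.iloc[1, 0] = np.nan
        d = abc_distance(sim, obs)
        assert d[0] == 0.0 and np.isinf(d[1])

    def test_scales_standardise(self):
        obs = pd.Series(0.0, index=list(SUMMARY_STATS))
        sim = obs + 2.0
        d = abc_distance(sim, obs, scales=np.full(9, 2.0))
        assert d == pytest.approx(9.0)


class TestReject:
    def test_fraction_of_thousand(self):
        rng = np.random.default_rng(0)
        d = rng.random(1000)
        mask = reject(d, 0.10)
        assert mask.sum() == 100
        assert d[mask].max() <= np.sort(d)[100]

    def test_all_equal_ties_broken_by_index(self):
        mask = reject(np.ones(50), 0.10)
        assert mask[:5].all() and not mask[5:].any()

    def test_fraction_one_accepts_all(self):
        assert reject(np.arange(20), 1.0).all()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            reject(np.arange(20), 0.0)

    def test_too_few_simulations_rejected(self):
        with pytest.raises(ValueError):
            reject(np.arange(5), 0.5)


class TestScenarioLikelihood:
    def test_observed_inside_cloud_scores_higher(self):
        rng = np.random.default_rng(1)
        cloud = rng.normal(0, 1, size=(200, 9))
        inside = scenario_likelihood(cloud, np.zeros(9))
        outside = scenario_likelihood(cloud, np.full(9, 50.0))
        assert inside > outside

    def test_identical_clouds_give_equal_likelihood(self):
        rng = np.random.default_rng(2)
        cloud = rng.normal(0, 1, size=(100, 9))
        obs = np.full(9, 0.3)
        assert scenario_likelihood(cloud, obs) == scenario_likelihood(cloud.copy(), obs)

    def test_too_few_accepted_rejected(self):
        with pytest.raises(ValueError):
            scenario_likelihood(np.zeros((10, 9)), np.zeros(9))

    def test_degenerate_dimension_warns_but_returns(self):
        rng = np.random.default_rng(3)
        cloud = rng.normal(0, 1, size=(50, 3))
        cloud[:, 1] = 4.2
        with pytest.warns(UserWarning, match="floor"):
            ll = scenario_likelihood(cloud, np.array([0.0, 4.2, 0.0]))
        assert np.isfinite(ll)


class TestPosteriorSummary:
    def test_uniform_grid_median(self):
        d = pd.DataFrame({"T": np.arange(10.0, 31.0)})
        s = posterior_summary(d)
        assert s.loc["T", "median"] == 20.0

    def test_point_mass_has_zero_width(self):
        d = pd.DataFrame({"x": np.full(30, 0.4)})
        s = posterior_summary(d)
        assert s.loc["x", "lo95"] == s.loc["x", "hi95"] == 0.4

    def test_log_parameters_also_reported_in_log10(self):
        d = pd.DataFrame({"K": np.full(25, 100.0)})
        s = posterior_summary(d)
        assert s.loc["log10_K", "median"] == pytest.approx(2.0)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            posterior_summary(pd.DataFrame({"T": np.arange(5.0)}))


@pytest.fixture(scope="module")
def tiny_setup(graph):
    ss = make_samples(
        [("a", "Europe", 0.0), ("b", "Europe", 0.0), ("c", "MiddleEast", 0.0),
         ("d", "Beringia", 0.0), ("e", "Beringia", 10.0), ("f", "NorthAmerica", 0.0),
         ("g", "NorthAmerica", 4.0), ("h", "EastEurasia", 0.0)]
    )
    obs = pd.Series(
        {s: v for s, v in zip(
            SUMMARY_STATS, [1.0, 2.0, 3.0, 5.0, 5.0, 6.0, 5.0, 6.0, 4.0])}
    )
    return ss, obs


class TestRunAbc:
    def test_bit_reproducible_and_order_independent(self, graph, tiny_setup):
        ss, obs = tiny_setup
        scens = [("static", None), ("expansion", "Beringia")]
        r1 = run_abc(obs, ss, graph=graph, scenarios=scens, n_sims=300, seed=11)
        r2 = run_abc(obs, ss, graph=graph, scenarios=scens, n_sims=300, seed=11)
        pd.testing.assert_series_equal(r1.log_likelihoods, r2.log_likelihoods)
        # scenario order must not matter for per-scenario results
        r3 = run_abc(obs, ss, graph=graph, scenarios=scens[::-1], n_sims=300, seed=11)
        assert r3.log_likelihoods["expansion[Beringia]"] == r1.log_likelihoods["expansion[Beringia]"]

    def test_acceptance_count_and_bf_normalisation(self, graph, tiny_setup):
        ss, obs = tiny_setup
        r = run_abc(
            obs, ss, graph=graph, scenarios=[("static", None), ("bottleneck", None)],
            n_sims=250, acceptance_fraction=0.10, seed=5,
        )
        for label, t in r.tables.items():
            assert t["accepted"].sum() == 25
        bf = r.bayes_factors
        assert bf.max() == 1.0
        assert (bf >= 0).all()
        assert r.best == bf.idxmax()
        assert r.epsilon > 0
        assert r.ball_counts.sum() >= 1

    def test_posterior_accessor(self, graph, tiny_setup):
        ss, obs = tiny_setup
        r = run_abc(obs, ss, graph=graph, scenarios=[("static", None)], n_sims=250, seed=2)
        post = r.posterior("static")
        assert {"m", "K", "log10_m", "log10_K"} == set(post.index)
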