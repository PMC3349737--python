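import numpy as np
import pandas as pd
import pytest

import oracles
from maluspop.abc_inference import (AnalysisConfig, DemographicPriors,
                                    ObservedStats, ReferenceTable,
                                    build_reference_table,
                                    generations_to_years, model_posterior,
                                    param_posterior,
                                    posterior_predictive_check, stat_labels,
                                    summary_stats)
from conftest import make_table, random_table


class TestGenerationsToYears:
    @pytest.mark.parametrize("gens,years", [(2360, 17700), (600, 4500),
                                            (0, 0)])
    def test_printed_conversions(self, gens, years):
        cfg = AnalysisConfig()
        assert generations_to_years(gens, cfg) == years

    def test_custom_generation_time(self):
        cfg = AnalysisConfig(generation_time=5.0)
        assert generations_to_years(100, cfg) == 500

    def test_positive_generation_time_required(self):
        with pytest.raises(ValueError):
            AnalysisConfig(generation_time=0)


class TestSummaryStats:
    def test_label_layout(self, rng):
        table, pops = random_table(rng, 12, 3, n_pops=3)
        st = summary_stats(table, pops)
        P = 3
        assert len(st.labels) == 2 * P + 2 * (P * (P - 1) // 2)
        assert st.labels == stat_labels(pops.labels())

    def test_identical_populations(self, rng):
        # identical genotype multisets: theta within its O(1/n) sampling bias
        g = rng.choice(100 + 2 * np.arange(5), size=(60, 4, 2)).astype(np.int32)
        calls = np.vstack([g, g])
        table, pops = make_table(calls, pops=["A"] * 60 + ["B"] * 60)
        s = summary_stats(table, pops).as_series()
        assert abs(s["FST_A_B"]) <= 0.02
        assert s["dmu2_A_B"] == 0.0

    def test_fixed_repeat_difference(self):
        # pop A all 10 repeats (120 nt), pop B all 13 repeats (126 nt)
        table, pops = make_table([[(120, 120)]] * 3 + [[(126, 126)]] * 3,
                                 pops=["A"] * 3 + ["B"] * 3)
        s = summary_stats(table, pops).as_series()
        assert s["dmu2_A_B"] == pytest.approx(9.0, abs=1e-12)

    def test_matches_direct_oracle(self, rng):
        table, pops = random_table(rng, 14, 3, n_alleles=4, n_pops=2)
        s = summary_stats(table, pops).as_series()
        from maluspop.popgen_stats import _pop_genotypes
        by = _pop_genotypes(table, pops)
        genosA = [[tuple(int(x) for x in g) for g in l] for l in by["pop0"]]
        genosB = [[tuple(int(x) for x in g) for g in l] for l in by["pop1"]]
        want_theta = oracles.theta_multilocus(list(zip(genosA, genosB)))
        assert s["FST_pop0_pop1"] == pytest.approx(want_theta, abs=1e-12)
        # mean alleles/locus and Nei diversity, direct formulas
        for p, genos in (("pop0", genosA), ("pop1", genosB)):
            ks, hs = [], []
            for l in genos:
                copies = [a for g in l for a in g]
                ks.append(len(set(copies)))
                n = len(copies)
                ssq = sum((copies.count(al) / n) ** 2 for al in set(copies))
                hs.append(n * (1 - ssq) / (n - 1))
            assert s[f"A_{p}"] == pytest.approx(np.mean(ks), abs=1e-12)
            assert s[f"H_{p}"] == pytest.approx(np.mean(hs), abs=1e-12)
        # Goldstein distance from mean repeat counts
        d2 = []
        for j, (la, lb) in enumerate(zip(genosA, genosB)):
            ra = np.mean([(a - 100) / 2 for g in la for a in g])
            rb = np.mean([(a - 100) / 2 for g in lb for a in g])
            d2.append((ra - rb) ** 2)
        assert s["dmu2_pop0_pop1"] == pytest.approx(np.mean(d2), abs=1e-12)


def _synthetic_ref(rng, model_id, n, shift=0.0):
    S = 6
    stats = rng.normal(size=(n, S)) + shift
    params = pd.DataFrame({
        "N1": rng.uniform(10, 1e5, n),
        "T3": rng.uniform(200, 1e4, n),
        "r2": rng.uniform(0, 1, n),
        "mu_mean": rng.uniform(1e-4, 1e-3, n),
    })
    bounds = {"N1": (10.0, 1e5, False), "T3": (200.0, 1e4, False),
              "r2": (0.0, 1.0, False), "mu_mean": (1e-4, 1e-3, False)}
    return ReferenceTable(model_id, params, stats,
                          [f"s{i}" for i in range(S)], bounds, n)


class TestModelPosterior:
    def test_duplicated_tables_are_symmetric(self, rng):
        ra = _synthetic_ref(rng, "a", 4000)
        rb = ReferenceTable("b", ra.params.copy(), ra.stats.copy(),
                            ra.stat_labels, ra.prior_bounds, ra.n_sims)
        obs = ObservedStats(np.zeros(6), ra.stat_labels)
        post = model_posterior([ra, rb], obs, AnalysisConfig(tolerance_frac=0.05))
        assert post.table["p"].sum() == pytest.approx(1.0, abs=1e-6)
        assert post.table.loc["a", "p"] == pytest.approx(0.5, abs=0.05)

    def test_ci_contains_point_estimate(self, rng):
        ra = _synthetic_ref(rng, "a", 3000)
        rb = _synthetic_ref(rng, "b", 3000, shift=0.5)
        obs = ObservedStats(np.zeros(6), ra.stat_labels)
        post = model_posterior([ra, rb], obs, AnalysisConfig(tolerance_frac=0.05))
        t = post.table
        assert ((t["ci2.5"] <= t["p"] + 1e-9) &
                (t["p"] <= t["ci97.5"] + 1e-9)).all()

    def test_uninformative_stats_reduce_to_rejection_frequencies(self, rng):
        # constant statistics: the regression has intercepts only
        ra = _synthetic_ref(rng, "a", 2000)
        rb = _synthetic_ref(rng, "b", 1000)
        ra.stats[:] = 0.0
        rb.stats[:] = 0.0
        obs = ObservedStats(np.zeros(6), ra.stat_labels)
        post = model_posterior([ra, rb], obs, AnalysisConfig(tolerance_frac=0.5))
        assert post.table.loc["a", "p"] == pytest.approx(2 / 3, abs=0.1)

    def test_mismatched_labels_rejected(self, rng):
        ra = _synthetic_ref(rng, "a", 500)
        rb = _synthetic_ref(rng, "b", 500)
        rb.stat_labels = list(rb.stat_labels)[::-1]
        obs = ObservedStats(np.zeros(6), ra.stat_labels)
        with pytest.raises(ValueError):
            model_posterior([ra, rb], obs, AnalysisConfig(tolerance_frac=0.1))


class TestParamPosterior:
    def test_no_update_limit_returns_prior(self, rng):
        ref = _synthetic_ref(rng, "c", 5000)
        obs = ObservedStats(np.zeros(6), ref.stat_labels)
        post = param_posterior(ref, obs, AnalysisConfig(tolerance_frac=1.0),
                               adjust=False, kernel="uniform")
        from scipy.stats import kstest
        u = (post.draws["N1"] - 10) / (1e5 - 10)
        assert kstest(u, "uniform").statistic < 0.05

    def test_adjusted_draws_respect_prior_bounds(self, rng):
        ref = _synthetic_ref(rng, "c", 3000)
        obs = ObservedStats(np.full(6, 0.3), ref.stat_labels)
        post = param_posterior(ref, obs, AnalysisConfig(tolerance_frac=0.1))
        assert post.adjusted
        assert ((post.draws["r2"] > 0) & (post.draws["r2"] < 1)).all()
        assert ((post.draws["N1"] > 10) & (post.draws["N1"] < 1e5)).all()

    def test_affine_equivariance_of_statistics(self, rng):
        ref = _synthetic_ref(rng, "c", 3000)
        obs = ObservedStats(np.full(6, 0.2), ref.stat_labels)
        cfg = AnalysisConfig(tolerance_frac=0.1)
        post1 = param_posterior(ref, obs, cfg)
        ref2 = ReferenceTable(ref.model_id, ref.params, ref.stats.copy(),
                              ref.stat_labels, ref.prior_bounds, ref.n_sims)
        ref2.stats[:, 2] = 7.0 - 3.0 * ref2.stats[:, 2]
        obs2 = ObservedStats(obs.values.copy(), ref.stat_labels)
        obs2.values[2] = 7.0 - 3.0 * obs2.values[2]
        post2 = param_posterior(ref2, obs2, cfg)
        assert np.allclose(post1.draws.to_numpy(), post2.draws.to_numpy(),
                           atol=1e-9)

    def test_composites_computed_per_draw(self, rng):
        ref = _synthetic_ref(rng, "c", 2000)
        obs = ObservedStats(np.zeros(6), ref.stat_labels)
        post = param_posterior(ref, obs, AnalysisConfig(tolerance_frac=0.2))
        assert np.allclose(post.draws["theta1"],
                           4 * post.draws["N1"] * post.draws["mu_mean"])
        assert np.allclose(post.draws["tau3"],
                           post.draws["mu_mean"] * post.draws["T3"])

    def test_summary_ci_orders(self, rng):
        ref = _synthetic_ref(rng, "c", 2000)
        obs = ObservedStats(np.zeros(6), ref.stat_labels)
        post = param_posterior(ref, obs, AnalysisConfig(tolerance_frac=0.2))
        assert (post.summary["ci2.5"] <= post.summary["ci97.5"]).all()


class TestPriors:
    def test_time_ordering_holds_in_draws(self, rng):
        priors = DemographicPriors()
        for _ in range(300):
            scen, p = priors.draw_scenario("a", rng)
            assert p["T3"] < p["T2"] < p["T1"]
            assert p["T3"] > 600  # dom must exist at the 600-generation pulse

    def test_marginals_match_uniform_priors(self, rng):
        priors = DemographicPriors()
        from scipy.stats import kstest
        draws = [priors.draw_scenario("d", rng)[1] for _ in range(4000)]
        n1 = np.array([d["N1"] for d in draws])
        # N1 is unconstrained by the ordering rejection
        assert kstest((n1 - 10) / (1e5 - 10), "uniform").statistic < 0.05

    def test_model_parameter_lists(self):
        priors = DemographicPriors()
        assert priors.param_names("c")[7] == "r2"
        assert "r5" in priors.param_names("b")
        assert not any(k.startswith("r") for k in priors.param_names("d")
                       if k != "r2")


class TestReferenceTableAndPipeline:
    @pytest.fixture(scope="class")
    def small_ref(self):
        priors = DemographicPriors()
        samples = {"dom": 8, "ori": 8, "siev": 8, "sylv": 8}
        return build_reference_table("c", priors, samples, n_sims=400,
                                     seed=7, n_loci=6), samples

    def test_reference_table_shapes(self, small_ref):
        ref, _ = small_ref
        assert ref.stats.shape == (400, 2 * 4 + 2 * 6)
        assert len(ref.params) == 400
        assert set(ref.prior_bounds) == set(ref.params.columns)

    def test_build_is_deterministic(self):
        priors = DemographicPriors()
        samples = {"dom": 4, "ori": 4, "siev": 4, "sylv": 4}
        r1 = build_reference_table("d", priors, samples, n_sims=100, seed=3,
                                   n_loci=3)
        r2 = build_reference_table("d", priors, samples, n_sims=100, seed=3,
                                   n_loci=3)
        assert np.array_equal(r1.stats, r2.stats)
        assert r1.params.equals(r2.params)

    def test_posterior_predictive_check_self_consistency(self, small_ref):
        ref, samples = small_ref
        # observed data drawn from the same prior-predictive ensemble
        obs = ObservedStats(np.nanmedian(ref.stats, axis=0), ref.stat_labels)
        post = param_posterior(ref, obs, AnalysisConfig(tolerance_frac=0.25))
        tails = posterior_predictive_check("c", post, samples, obs,
                                           n_pods=40, seed=5, n_loci=6)
        inside = ((tails > 0.01) & (tails < 0.99)).mean()
        assert inside >= 0.85

    def test_posterior_predictive_flags_planted_misfit(self, small_ref):
        ref, samples = small_ref
        obs_vals = np.nanmedian(ref.stats, axis=0)
        mad = np.nanmedian(np.abs(ref.stats - obs_vals), axis=0)
        j = ref.stat_labels.index("FST_dom_sylv")
        obs_vals[j] += 5 * mad[j]
        obs = ObservedStats(obs_vals, ref.stat_labels)
        post = param_posterior(ref, obs, AnalysisConfig(tolerance_frac=0.25))
        tails = posterior_predictive_check("c", post, samples, obs,
                                           n_pods=40, seed=6, n_loci=6)
        assert tails[f"FST_dom_sylv"] > 0.9

    def test_zero_pods_rejected(self, small_ref):
        ref, samples = small_ref
        obs = ObservedStats(np.nanmedian(ref.stats, axis=0), ref.stat_labels)
        post = param_posterior(ref, obs, AnalysisConfig(tolerance_frac=0.25))
        with pytest.raises(ValueError):
            posterior_predictive_check("c", post, samples, obs, n_pods=0,
                                       seed=1, n_loci=6)

    def test_tolerance_shrink_moves_rejection_posterior_toward_truth(self):
        priors = DemographicPriors()
        samples = {"dom": 10, "ori": 10, "siev": 10, "sylv": 10}
        ref = build_reference_table("c", priors, samples, n_sims=1200,
                                    seed=11, n_loci=8)
        from maluspop.synthetic_data import make_pods
        truth = dict(N1=3000, N2=8000, N3=12000, N4=15000, T1=30000,
                     T2=5000, T3=2000, r2=0.6, mu_mean=3e-4, p_mean=0.2,
                     mu_sni_mean=1e-6)
        pod = make_pods("c", truth, samples, n_loci=8, seed=21)
        errs = []
        for tol in (0.5, 0.05):
            post = param_posterior(ref, pod.stats,
                                   AnalysisConfig(tolerance_frac=tol),
                                   adjust=False)
            errs.append(abs(post.draws["r2"].mean() - 0.6))
        assert errs[1] < errs[0]
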