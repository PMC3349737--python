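import numpy as np
import pytest

import oracles
from maluspop.popgen_stats import (assign_clones, diversity_summary,
                                   ewens_watterson_test,
                                   gaussian_relatedness_test,
                                   min_merge_threshold, null_allele_freq,
                                   pairwise_allele_distance,
                                   rarefied_richness, rxy_matrix, rxy_pairs,
                                   wc_fst, _multilocus_fis, _multilocus_theta,
                                   _pop_genotypes)
from conftest import make_table, random_table


def _geno_lists(table, pops):
    """Per-pop, per-locus genotype tuple lists for the oracle functions."""
    by_pop = _pop_genotypes(table, pops)
    return {p: [[tuple(g) for g in locus] for locus in per_locus]
            for p, per_locus in by_pop.items()}


class TestDiversity:
    def test_all_heterozygous_toy(self):
        # 4 diploids all 100/104: H_O = 1, unbiased H_E = (8/7)*0.5
        table, pops = make_table([[(100, 104)]] * 4)
        res = diversity_summary(table, pops, n_perm=200, seed=1)
        assert res.loc["pop", "H_O"] == 1.0
        assert res.loc["pop", "H_E"] == pytest.approx(8 / 7 * 0.5, abs=1e-12)
        assert res.loc["pop", "F_IS"] < 0

    def test_hardy_weinberg_proportions_match_oracle(self):
        # 1 AA, 2 AB, 1 BB: exact HW genotype proportions
        table, pops = make_table([[(100, 100)], [(100, 104)],
                                  [(100, 104)], [(104, 104)]])
        res = diversity_summary(table, pops, n_perm=0)
        expected = oracles.fis_multilocus([[(100, 100), (100, 104),
                                            (100, 104), (104, 104)]])
        assert res.loc["pop", "F_IS"] == pytest.approx(expected, abs=1e-9)

    def test_monomorphic_only(self):
        table, pops = make_table([[(100, 100)], [(100, 100)]])
        res = diversity_summary(table, pops, n_perm=0)
        assert res.loc["pop", "H_O"] == 0
        assert res.loc["pop", "H_E"] == 0
        assert np.isnan(res.loc["pop", "F_IS"])

    def test_single_individual_population_rejected(self):
        table, pops = make_table([[(100, 104)]])
        with pytest.raises(ValueError):
            diversity_summary(table, pops, n_perm=0)

    @pytest.mark.parametrize("seed", range(8))
    def test_fis_matches_oracle_on_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        table, pops = random_table(rng, int(rng.integers(2, 6)),
                                   int(rng.integers(1, 4)), n_alleles=3)
        genos = _geno_lists(table, pops)["pop"]
        got = _multilocus_fis(_pop_genotypes(table, pops)["pop"])
        want = oracles.fis_multilocus(genos)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)


class TestWcFst:
    def test_null_case_two_samples_from_one_pool(self, rng):
        lengths = 100 + 2 * np.arange(6)
        calls = rng.choice(lengths, size=(60, 8, 2)).astype(np.int32)
        table, pops = make_table(calls, pops=["A"] * 30 + ["B"] * 30)
        res = wc_fst(table, pops, n_perm=200, seed=3)
        assert res.theta.loc["A", "B"] <= 0.02
        assert res.pvalue.loc["A", "B"] > 0.05

    def test_fixed_difference(self):
        table, pops = make_table([[(100, 100)]] * 4 + [[(104, 104)]] * 4,
                                 pops=["A"] * 4 + ["B"] * 4)
        res = wc_fst(table, pops, n_perm=0)
        assert res.theta.loc["A", "B"] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_theta_matches_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        table, pops = random_table(rng, 8, 3, n_alleles=3, n_pops=2)
        by_pop = _pop_genotypes(table, pops)
        got = _multilocus_theta(by_pop["pop0"], by_pop["pop1"])
        genos = _geno_lists(table, pops)
        want = oracles.theta_multilocus(list(zip(genos["pop0"],
                                                 genos["pop1"])))
        assert got == pytest.approx(want, abs=1e-12)

    def test_absent_population_rejected(self, rng):
        table, pops = random_table(rng, 4, 2, n_pops=2)
        pops.mapping[table.individuals[1]] = "pop0"
        pops.mapping["ghost"] = "pop9"
        with pytest.raises(ValueError):
            wc_fst(table, pops, n_perm=0)


class TestRarefaction:
    def test_full_size_equals_observed_count(self):
        table, pops = make_table([[(100, 102)], [(104, 104)], [(100, 106)]])
        _, avg = rarefied_richness(table, pops, g=6)
        assert avg.loc["pop", "A_r"] == pytest.approx(4.0, abs=1e-12)

    def test_g_one_gives_one(self, rng):
        table, pops = random_table(rng, 6, 2, n_alleles=4)
        _, avg = rarefied_richness(table, pops, g=1)
        assert avg["A_r"].to_numpy() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        table, pops = random_table(rng, 8, 1, n_alleles=3, n_pops=2)
        g = int(rng.integers(2, 5))
        per_locus, _ = rarefied_richness(table, pops, g=g)
        by_pop = _pop_genotypes(table, pops)
        pop_copies = [[int(a) for a in by_pop[p][0].ravel()]
                      for p in ("pop0", "pop1")]
        a_r, a_p = oracles.exhaustive_richness(pop_copies, g)
        for pi, p in enumerate(("pop0", "pop1")):
            assert per_locus.loc[(p, "L00"), "A_r"] == \
                pytest.approx(a_r[pi], abs=1e-12)
            assert per_locus.loc[(p, "L00"), "A_p"] == \
                pytest.approx(a_p[pi], abs=1e-12)

    def test_monotone_in_g_and_private_bounded(self, rng):
        table, pops = random_table(rng, 10, 3, n_alleles=5, n_pops=2)
        prev = None
        for g in (2, 4, 6, 8):
            per_locus, avg = rarefied_richness(table, pops, g=g)
            assert (per_locus["A_p"] <= per_locus["A_r"] + 1e-12).all()
            if prev is not None:
                assert (avg["A_r"].to_numpy() >=
                        prev["A_r"].to_numpy() - 1e-12).all()
            prev = avg

    def test_invalid_g(self, rng):
        table, pops = random_table(rng, 4, 2)
        with pytest.raises(ValueError):
            rarefied_richness(table, pops, g=0)
        with pytest.raises(ValueError):
            rarefied_richness(table, pops, g=99)

    def test_subsampling_cross_check(self, rng):
        # rarefaction formula agrees with Monte-Carlo subsampling
        table, pops = random_table(rng, 12, 1, n_alleles=5)
        g = 6
        _, avg = rarefied_richness(table, pops, g=g)
        copies = table.locus_alleles(0)
        sims = np.array([np.unique(rng.choice(copies, g, replace=False)).size
                         for _ in range(20000)])
        se = sims.std() / np.sqrt(sims.size)
        assert abs(avg.loc["pop", "A_r"] - sims.mean()) < 3 * se + 1e-9


class TestNullAlleles:
    def test_equal_het_gives_zero(self):
        # all heterozygous 100/104: H_O=1 > H_E, floored at 0
        table, pops = make_table([[(100, 104)]] * 6)
        per_locus, mean = null_allele_freq(table, pops)
        assert per_locus.iloc[0, 0] == 0.0

    def test_no_heterozygotes_gives_one(self):
        table, pops = make_table([[(100, 100)], [(104, 104)]] * 3)
        per_locus, _ = null_allele_freq(table, pops)
        assert per_locus.iloc[0, 0] == pytest.approx(1.0)

    def test_formula_consistency(self, rng):
        table, pops = random_table(rng, 20, 4, n_alleles=4)
        div = diversity_summary(table, pops, n_perm=0)
        per_locus, mean = null_allele_freq(table, pops)
        by_pop = _pop_genotypes(table, pops)["pop"]
        from maluspop.popgen_stats import (nei_unbiased_diversity,
                                           observed_heterozygosity)
        for j, g in enumerate(by_pop):
            he = nei_unbiased_diversity(g.ravel())
            ho = observed_heterozygosity(g)
            want = max(0.0, (he - ho) / (he + ho)) if he > 0 else 0.0
            assert per_locus.iloc[j, 0] == pytest.approx(want, abs=1e-12)
        assert mean["pop"] == pytest.approx(per_locus["pop"].mean())


class TestRelatedness:
    def _simulate_pairs(self, rng, n_pairs, relation):
        lengths = (100 + 2 * np.arange(8)).astype(np.int32)
        L = 26
        rows = []
        pairs = []
        for i in range(n_pairs):
            p1 = rng.choice(lengths, size=(L, 2))
            p2 = rng.choice(lengths, size=(L, 2))
            if relation == "parent-offspring":
                off = np.stack([p1[np.arange(L), rng.integers(0, 2, L)],
                                p2[np.arange(L), rng.integers(0, 2, L)]], 1)
                rows += [p1, off]
            else:
                rows += [p1, p2]
            pairs.append((2 * i, 2 * i + 1))
        table, _ = make_table(np.stack(rows))
        return table, pairs

    def test_parent_offspring_near_half(self, rng):
        table, pairs = self._simulate_pairs(rng, 400, "parent-offspring")
        vals = rxy_pairs(table, pairs)
        assert abs(np.nanmean(vals) - 0.5) < 0.05

    def test_unrelated_near_zero(self, rng):
        table, pairs = self._simulate_pairs(rng, 400, "unrelated")
        vals = rxy_pairs(table, pairs)
        assert abs(np.nanmean(vals)) < 0.05

    def test_clone_pair_high(self, rng):
        lengths = (100 + 2 * np.arange(8)).astype(np.int32)
        g = rng.choice(lengths, size=(26, 2))
        table, _ = make_table(np.stack([g, g.copy()] +
                                       [rng.choice(lengths, size=(26, 2))
                                        for _ in range(6)]))
        vals = rxy_pairs(table, [(0, 1)])
        assert vals[0] > 0.9

    def test_matrix_symmetric(self, rng):
        table, _ = random_table(rng, 8, 10, n_alleles=6)
        m = rxy_matrix(table)
        assert np.allclose(m.to_numpy(), m.to_numpy().T, equal_nan=True)


class TestGaussianCheck:
    def test_returns_sample_sd(self, rng):
        x = rng.normal(0, 0.11, 200)
        _, sd = gaussian_relatedness_test(x, n_sim=100, seed=1)
        assert sd == pytest.approx(np.std(x, ddof=1), abs=1e-12)

    def test_null_p_values_centred(self):
        rng = np.random.default_rng(7)
        ps = [gaussian_relatedness_test(rng.normal(0, 0.11, 300),
                                        n_sim=300, seed=i)[0]
              for i in range(200)]
        assert abs(np.median(ps) - 0.5) <= 0.1

    def test_planted_cluster_detected(self, rng):
        x = np.concatenate([rng.normal(0, 0.11, 450),
                            0.5 + rng.normal(0, 0.01, 50)])
        p, _ = gaussian_relatedness_test(x, n_sim=3000, seed=2)
        assert p < 0.01

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            gaussian_relatedness_test(np.zeros(50))
        with pytest.raises(ValueError):
            gaussian_relatedness_test(np.ones(10))


class TestEwensWatterson:
    def test_single_allele(self):
        p = ewens_watterson_test([np.array([10])], n_sim=200, seed=0)
        assert p[0] == 1.0

    def test_more_alleles_than_genes_rejected(self):
        # four allele classes claimed for only two gene copies
        with pytest.raises(ValueError):
            ewens_watterson_test([np.array([1, 0, 0, 1])], n_sim=200, seed=0)

    def test_small_case_matches_exact_enumeration(self):
        # n=4, k=2: conditional ESF has two partitions {3,1}, {2,2}
        got = ewens_watterson_test([np.array([3, 1]), np.array([2, 2])],
                                   n_sim=100000, seed=5)
        want_31 = oracles.ewens_two_sided_p(4, 2, 0.625)
        want_22 = oracles.ewens_two_sided_p(4, 2, 0.5)
        assert got[0] == pytest.approx(want_31, abs=0.02)
        assert got[1] == pytest.approx(want_22, abs=0.02)

    def test_neutral_calibration(self, rng):
        # loci drawn from the Ewens distribution itself: ~5% rejection
        from maluspop.popgen_stats import _urn_homozygosity, _theta_for_k
        theta = 3.0
        counts = []
        for _ in range(500):
            c = np.zeros(60, dtype=int)
            # one urn replicate
            n = 50
            tables = [1]
            for i in range(1, n):
                if rng.random() < theta / (theta + i):
                    tables.append(1)
                else:
                    probs = np.array(tables) / i
                    tables[rng.choice(len(tables), p=probs)] += 1
            counts.append(np.array(sorted(tables, reverse=True)))
        ps = ewens_watterson_test(counts, n_sim=4000, seed=11)
        rej = np.mean(ps < 0.05)
        assert abs(rej - 0.05) <= 0.04


class TestClones:
    def test_identical_merge_at_zero(self, rng):
        g = rng.integers(100, 120, size=(1, 5, 2)).astype(np.int32)
        table, _ = make_table(np.vstack([g, g]))
        part = assign_clones(table, threshold=0)
        assert part.lineage["ind000"] == part.lineage["ind001"]

    def test_three_slot_difference_threshold(self):
        g1 = [[100, 100], [102, 104], [106, 106], [108, 110]]
        g2 = [[100, 102], [102, 106], [106, 106], [104, 110]]
        table, _ = make_table([g1, g2])
        d = pairwise_allele_distance(table)[0, 1]
        assert d == 3
        assert assign_clones(table, 3).lineage["ind000"] == \
            assign_clones(table, 3).lineage["ind001"]
        p2 = assign_clones(table, 2)
        assert p2.lineage["ind000"] != p2.lineage["ind001"]

    def test_partition_matches_graph_oracle(self, rng):
        table, _ = random_table(rng, 30, 4, n_alleles=3, missing_frac=0.1)
        thr = 5
        part = assign_clones(table, thr)
        genos = [[tuple(table.calls[i, j]) for j in range(table.n_loci)]
                 for i in range(30)]
        dist = [[oracles.allele_mismatch(genos[i], genos[j])
                 for j in range(30)] for i in range(30)]
        want = oracles.brute_force_components(dist, thr)
        got = {frozenset(np.flatnonzero(
            [part.lineage[ind] == g for ind in table.individuals]))
            for g in set(part.lineage.values())}
        assert got == want

    def test_invariant_under_reordering(self, rng):
        table, _ = random_table(rng, 20, 4, n_alleles=3)
        part1 = assign_clones(table, 4)
        perm = rng.permutation(20)
        shuffled = table.subset(perm)
        part2 = assign_clones(shuffled, 4)
        assert part1.groups() == part2.groups()

    def test_min_merge_threshold(self, rng):
        table, _ = random_table(rng, 10, 4, n_alleles=3)
        t = min_merge_threshold(table)
        D = pairwise_allele_distance(table)
        iu = np.triu_indices(10, 1)
        assert t == D[iu].min()
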