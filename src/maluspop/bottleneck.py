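"""Heterozygosity-excess bottleneck test under SMM and TPM mutation models.

For each polymorphic locus the gene diversity expected at mutation-drift
equilibrium (H_eq) given the observed number of alleles k and sample size n is
estimated by conditional coalescent simulation: standard single-population
genealogies are overlaid with stepwise mutations at a rate tuned by bisection
so that the expected allele count is k, and replicates with exactly k alleles
are retained.  A recent contraction leaves H_E (from allele frequencies) above
H_eq (from k and n); a one-tailed Wilcoxon signed-rank test over loci detects
a significant excess.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import wilcoxon

from .genotype_io import MISSING, GenotypeTable, PopulationMap
from .popgen_stats import _pop_genotypes, nei_unbiased_diversity

__all__ = ["MutationModel", "SMM", "TPM", "equilibrium_het_given_k",
           "het_excess_test", "simulate_bottleneck_dataset",
           "BottleneckResult"]


@dataclass(frozen=True)
class MutationModel:
    """Microsatellite mutation model for equilibrium simulation.

    ``smm`` changes repeat counts by exactly one unit per mutation.  ``tpm``
    is a two-phase model: with probability ``p_multi`` the step magnitude is
    geometric, parametrized by its variance ``var_geom`` (the convention of
    the classical heterozygosity-excess software), otherwise a single step.
    """

    name: str = "smm"
    p_multi: float = 0.30
    var_geom: float = 30.0

    def __post_init__(self):
        if self.name not in ("smm", "tpm"):
            raise ValueError("model name must be 'smm' or 'tpm'")
        if not 0 <= self.p_multi <= 1 or self.var_geom <= 0:
            raise ValueError("invalid TPM parameters")

    @property
    def effective_p_multi(self) -> float:
        return 0.0 if self.name == "smm" else self.p_multi

    @property
    def p_geom(self) -> float:
        """Geometric parameter giving multistep variance ``var_geom``."""
        v = self.var_geom
        return (-1.0 + np.sqrt(1.0 + 4.0 * v)) / (2.0 * v)

    def key(self) -> str:
        return f"{self.name}:{self.effective_p_multi}:{self.var_geom}"


SMM = MutationModel("smm")
TPM = MutationModel("tpm", p_multi=0.30, var_geom=30.0)


@njit(cache=True)
def _sim_locus(n, epoch_times, epoch_sizes, mu, p_multi, p_geom,
               seed):  # pragma: no cover - numba
    """One coalescent locus in a single population with piecewise-constant size.

    Time is in generations; coalescence rate k(k-1)/(4N(t)); mutations are a
    Poisson overlay of rate ``mu`` per lineage-generation, with step sizes in
    repeat units (unbounded range).  Returns the n sampled repeat states.
    """
    np.random.seed(seed)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    times = np.zeros(n_nodes)
    active = np.arange(n)
    k = n
    t = 0.0
    nxt = n
    while k > 1:
        # find current epoch
        ei = 0
        for e in range(epoch_times.size):
            if t >= epoch_times[e]:
                ei = e
        rate = k * (k - 1) / (4.0 * epoch_sizes[ei])
        wait = np.random.exponential(1.0 / rate)
        if ei + 1 < epoch_times.size and t + wait > epoch_times[ei + 1]:
            t = epoch_times[ei + 1]
            continue
        t += wait
        i = np.random.randint(k)
        j = np.random.randint(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = nxt
        parent[b] = nxt
        times[nxt] = t
        lo, hi = (i, j) if i < j else (j, i)
        active[lo] = nxt
        active[hi] = active[k - 1]
        nxt += 1
        k -= 1
    # mutation overlay: nodes were created in increasing time, so walking ids
    # from the root downward always visits a parent before its children
    states = np.zeros(n_nodes, dtype=np.int64)
    for v in range(n_nodes - 2, -1, -1):
        s = states[parent[v]]
        n_mut = np.random.poisson(mu * (times[parent[v]] - times[v]))
        for _ in range(n_mut):
            mag = 1
            if p_multi > 0.0 and np.random.random() < p_multi:
                mag = np.random.geometric(p_geom)
            if np.random.random() < 0.5:
                s += mag
            else:
                s -= mag
        states[v] = s
    return states[:n]


def _stable_seed(*parts) -> int:
    return zlib.crc32(",".join(str(p) for p in parts).encode()) % (2**31 - 1) + 1


_REF_N = 1000.0  # reference population size; only theta = 4*N*mu matters


def _batch_h_and_k(n, theta, model, reps, seed):
    mu = theta / (4.0 * _REF_N)
    et = np.array([0.0])
    es = np.array([_REF_N])
    h = np.empty(reps)
    k = np.empty(reps, dtype=int)
    for r in range(reps):
        states = _sim_locus(n, et, es, mu, model.effective_p_multi,
                            model.p_geom, (seed + 7919 * r) % (2**31 - 1) + 1)
        al, ct = np.unique(states, return_counts=True)
        p = ct / n
        h[r] = n * (1.0 - p @ p) / (n - 1)
        k[r] = al.size
    return h, k


def equilibrium_het_given_k(n: int, k: int, model: MutationModel = SMM,
                            reps: int = 1000, seed: int = 0,
                            max_batches: int = 60):
    """Mean and sd of equilibrium gene diversity conditional on k alleles.

    The mutation rate is tuned by bisection on theta so the expected allele
    count is about ``k``; replicates with exactly ``k`` distinct alleles are
    retained until ``reps`` are collected.  Returns ``(mean, sd, median)`` of
    the retained gene diversities: the distribution of H given k is
    left-skewed, and the signed-rank excess test centres each locus on the
    conditional median so its null is sign-balanced.
    """
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if k == 1:
        return 0.0, 0.0, 0.0
    if k == n:
        # every allele a singleton: unbiased H = n(1 - 1/n)/(n-1) = 1 exactly,
        # whatever the mutation rate
        return 1.0, 0.0, 1.0
    # bisection on log-theta against the simulated mean allele count
    lo, hi = 1e-3, 2e4
    pilot = 200
    for it in range(18):
        mid = float(np.sqrt(lo * hi))
        _, kk = _batch_h_and_k(n, mid, model, pilot,
                               _stable_seed("tune", n, k, model.key(), seed, it))
        if kk.mean() < k:
            lo = mid
        else:
            hi = mid
    theta = float(np.sqrt(lo * hi))

    kept = []
    got = 0
    for b in range(max_batches):
        h, kk = _batch_h_and_k(n, theta, model, max(reps, 500),
                               _stable_seed("run", n, k, model.key(), seed, b))
        kept.append(h[kk == k])
        got += kept[-1].size
        if got >= reps:
            break
    h_all = np.concatenate(kept)[:reps]
    if h_all.size < reps:
        raise RuntimeError(
            f"could not condition on k={k} alleles for n={n} "
            f"(retained {h_all.size} of {reps} after {max_batches} batches; "
            f"tuned theta={theta:.4g})")
    return float(h_all.mean()), float(h_all.std(ddof=1)), float(np.median(h_all))


# cache shared across datasets: H_eq depends only on (n, k, model, reps, seed)
_HEQ_CACHE: dict[tuple, tuple[float, float, float]] = {}


def _heq_cached(n, k, model, reps, seed):
    key = (n, k, model.key(), reps, seed)
    if key not in _HEQ_CACHE:
        _HEQ_CACHE[key] = equilibrium_het_given_k(n, k, model, reps, seed)
    return _HEQ_CACHE[key]


@dataclass
class BottleneckResult:
    """Per-locus detail and per-population one-tailed Wilcoxon p-values."""

    per_locus: pd.DataFrame
    pvalues: pd.Series
    model: MutationModel
    seed: int


def het_excess_test(table: GenotypeTable, pops: PopulationMap,
                    model: MutationModel = SMM, reps: int = 1000,
                    seed: int = 0) -> BottleneckResult:
    """Heterozygosity-excess test per population.

    For every polymorphic locus, the observed unbiased gene diversity H_E is
    compared with the simulated equilibrium H_eq given the observed (n, k);
    a one-tailed Wilcoxon signed-rank test (alternative: excess, H_E > H_eq)
    combines loci.  Monomorphic loci are excluded; at least four polymorphic
    loci are required per population.
    """
    by_pop = _pop_genotypes(table, pops)
    rows = []
    pvals = {}
    any_poly = False
    for pop, per_locus in by_pop.items():
        diffs = []
        for j, g in enumerate(per_locus):
            alleles = g.ravel()
            alleles = alleles[alleles != MISSING]
            n = alleles.size
            if n < 4:
                continue
            k = np.unique(alleles).size
            if k < 2:
                continue
            any_poly = True
            he = nei_unbiased_diversity(alleles)
            heq, sd, hmed = _heq_cached(n, k, model, reps, seed)
            std = (he - heq) / sd if sd > 0 else np.nan
            rows.append((pop, table.loci[j].name, n, k, he, heq, sd, std))
            # centre on the conditional median: H | k is left-skewed, and the
            # signed-rank null requires sign balance at equilibrium
            if sd > 0:
                diffs.append((he - hmed) / sd)
        if len(diffs) < 4:
            pvals[pop] = np.nan
            continue
        # rank the standardized differences, as the classical test does
        d = np.asarray(diffs)
        d = d[d != 0]
        pvals[pop] = float(wilcoxon(d, alternative="greater").pvalue) \
            if d.size else 1.0
    if not any_poly:
        raise ValueError("all loci monomorphic in every population")
    per_locus = pd.DataFrame(
        rows, columns=["population", "locus", "n_genes", "k", "H_E",
                       "H_eq_mean", "H_eq_sd", "std_diff"])
    return BottleneckResult(per_locus=per_locus,
                            pvalues=pd.Series(pvals, name="p_excess"),
                            model=model, seed=seed)


def simulate_bottleneck_dataset(n_dip: int, n_loci: int, theta: float,
                                model: MutationModel = SMM, seed: int = 0,
                                crash_factor: float | None = None,
                                crash_time_frac: float = 0.25,
                                rate_shape: float = 2.0):
    """Simulate a single-population microsatellite dataset for test purposes.

    At equilibrium (``crash_factor=None``) the population has constant size N
    with mean scaled mutation rate ``theta = 4 N mu``; per-locus rates vary as
    Gamma(shape ``rate_shape``, mean mu), as microsatellite panels do.  With
    ``crash_factor`` set, the population of size N crashed from an ancestral
    size ``crash_factor * N`` at ``crash_time_frac * N`` generations before
    the present (``theta`` still refers to the current population).  Returns a
    (GenotypeTable, PopulationMap) with alleles encoded as 500 + repeat state
    (motif length 1).
    """
    from .genotype_io import LocusDef

    N = _REF_N
    mu = theta / (4.0 * N)
    if crash_factor is None:
        et, es = np.array([0.0]), np.array([N])
    else:
        et = np.array([0.0, crash_time_frac * N])
        es = np.array([N, N * crash_factor])
    rng = np.random.default_rng(seed)
    n = 2 * n_dip
    calls = np.empty((n_dip, n_loci, 2), dtype=np.int32)
    for j in range(n_loci):
        mu_l = rng.gamma(rate_shape, mu / rate_shape)
        states = _sim_locus(n, et, es, mu_l, model.effective_p_multi,
                            model.p_geom, _stable_seed("data", seed, j))
        calls[:, j, :] = (states + 500).reshape(n_dip, 2)
    inds = [f"ind_{i:04d}" for i in range(n_dip)]
    loci = [LocusDef(f"L{j:02d}", motif_len=1, n_states=1000, min_len=1)
            for j in range(n_loci)]
    table = GenotypeTable(inds, loci, calls)
    return table, PopulationMap({i: "pop" for i in inds})
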