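"""Diversity, differentiation, relatedness, neutrality and clonality statistics.

Estimators follow the population-genetics standards for codominant
microsatellite data: Nei's unbiased gene diversity, Weir & Cockerham (1984)
variance-component F-statistics, rarefaction-based allelic richness and
private-allele richness, the Chakraborty null-allele estimator, the
Lynch & Ritland (1999) pairwise relatedness regression estimator, the
Ewens-Watterson homozygosity test, and single-linkage clonal assignment on
allele-mismatch distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotype_io import MISSING, GenotypeTable, PopulationMap

__all__ = [
    "diversity_summary", "wc_fst", "rarefied_richness", "null_allele_freq",
    "rxy_matrix", "rxy_pairs", "allele_frequencies",
    "gaussian_relatedness_test", "ewens_watterson_test",
    "assign_clones", "min_merge_threshold", "pairwise_allele_distance",
    "FstMatrix", "ClonalPartition",
]


# ---------------------------------------------------------------------------
# Basic helpers
# ---------------------------------------------------------------------------

def _pop_genotypes(table: GenotypeTable, pops: PopulationMap,
                   labels: list[str] | None = None):
    """Per-population, per-locus genotype arrays with missing rows dropped.

    Returns ``{pop: [array (n_scored, 2), ...]}`` over loci.
    """
    pops.validate(table)
    labels = labels or pops.labels()
    idx = {p: [] for p in labels}
    for i, ind in enumerate(table.individuals):
        p = pops[ind]
        if p in idx:
            idx[p].append(i)
    out = {}
    for p in labels:
        rows = np.asarray(idx[p], dtype=int)
        per_locus = []
        for j in range(table.n_loci):
            g = table.calls[rows, j, :]
            per_locus.append(g[g[:, 0] != MISSING])
        out[p] = per_locus
    return out


def nei_unbiased_diversity(alleles: np.ndarray) -> float:
    """Nei's unbiased gene diversity ``n (1 - sum p^2) / (n - 1)`` over gene copies."""
    n = alleles.size
    if n < 2:
        return np.nan
    _, counts = np.unique(alleles, return_counts=True)
    p = counts / n
    return n * (1.0 - float(p @ p)) / (n - 1)


def observed_heterozygosity(genos: np.ndarray) -> float:
    """Proportion of heterozygous genotypes among scored individuals."""
    if len(genos) == 0:
        return np.nan
    return float(np.mean(genos[:, 0] != genos[:, 1]))


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components
# ---------------------------------------------------------------------------

def _wc_components_locus(genos_by_pop: list[np.ndarray]):
    """Summed Weir-Cockerham variance components (a, b, c) at one locus.

    ``genos_by_pop`` holds one ``(n_i, 2)`` genotype array per population
    (missing already removed).  Components are summed over alleles.  With a
    single population the among-population component ``a`` is zero and the
    ``s^2`` terms vanish, giving the within-population decomposition used for
    per-population F_IS.
    """
    pops = [g for g in genos_by_pop if len(g) > 0]
    r = len(pops)
    if r == 0:
        return 0.0, 0.0, 0.0
    n = np.array([len(g) for g in pops], dtype=float)
    alleles = np.unique(np.concatenate([g.ravel() for g in pops]))
    if alleles.size < 2:
        return 0.0, 0.0, 0.0
    # freq and heterozygote-carrier proportion per pop per allele
    p = np.empty((r, alleles.size))
    h = np.empty((r, alleles.size))
    for i, g in enumerate(pops):
        ai = np.searchsorted(alleles, g)
        p[i] = np.bincount(ai.ravel(), minlength=alleles.size) / (2 * len(g))
        het = g[:, 0] != g[:, 1]
        hc = np.zeros(alleles.size)
        if het.any():
            hg = ai[het]
            hc = (np.bincount(hg[:, 0], minlength=alleles.size)
                  + np.bincount(hg[:, 1], minlength=alleles.size))
        h[i] = hc / len(g)

    nsum = n.sum()
    nbar = nsum / r
    pbar = (n[:, None] * p).sum(axis=0) / nsum
    hbar = (n[:, None] * h).sum(axis=0) / nsum
    if r > 1:
        nc = (nsum - (n @ n) / nsum) / (r - 1)
        s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
    else:
        if nbar < 2:
            return 0.0, 0.0, 0.0
        a = np.zeros_like(pbar)
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def _multilocus_fis(per_locus_genos: list[np.ndarray]) -> float:
    bsum = csum = 0.0
    for g in per_locus_genos:
        _, b, c = _wc_components_locus([g])
        bsum += b
        csum += c
    if bsum + csum == 0:
        return np.nan
    return 1.0 - csum / (bsum + csum)


def _multilocus_theta(genos_a: list[np.ndarray], genos_b: list[np.ndarray]) -> float:
    asum = dsum = 0.0
    for ga, gb in zip(genos_a, genos_b):
        a, b, c = _wc_components_locus([ga, gb])
        asum += a
        dsum += a + b + c
    if dsum == 0:
        return np.nan
    return asum / dsum


# ---------------------------------------------------------------------------
# Diversity summary (H_O, H_E, F_IS with permutation test)
# ---------------------------------------------------------------------------

def diversity_summary(table: GenotypeTable, pops: PopulationMap,
                      n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-population H_O, unbiased H_E, and Weir-Cockerham F_IS.

    H_O and H_E are averaged over polymorphic-or-not loci with at least two
    scored individuals; F_IS combines variance components over loci
    (monomorphic loci contribute nothing and are effectively excluded).  The
    permutation p-value is the fraction of within-population allele shuffles
    (re-pairing gene copies into pseudo-genotypes) with F_IS at least as large
    as observed, with the observed arrangement counted (+1 convention).
    """
    rng = np.random.default_rng(seed)
    by_pop = _pop_genotypes(table, pops)
    rows = []
    for pop, per_locus in by_pop.items():
        if max((len(g) for g in per_locus), default=0) < 2:
            raise ValueError(f"population {pop!r} has <2 scored individuals")
        ho = np.nanmean([observed_heterozygosity(g) for g in per_locus])
        he = np.nanmean([nei_unbiased_diversity(g.ravel()) for g in per_locus])
        fis = _multilocus_fis(per_locus)
        if n_perm > 0 and np.isfinite(fis):
            ge = 0
            for _ in range(n_perm):
                shuffled = []
                for g in per_locus:
                    pool = rng.permutation(g.ravel())
                    shuffled.append(pool.reshape(-1, 2))
                if _multilocus_fis(shuffled) >= fis:
                    ge += 1
            pval = (1 + ge) / (n_perm + 1)
        else:
            pval = np.nan
        rows.append((pop, ho, he, fis, pval))
    return pd.DataFrame(rows, columns=["population", "H_O", "H_E", "F_IS",
                                       "F_IS_p"]).set_index("population")


# ---------------------------------------------------------------------------
# Pairwise F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstMatrix:
    """Pairwise Weir-Cockerham theta with permutation p-values."""

    theta: pd.DataFrame
    pvalue: pd.DataFrame


def wc_fst(table: GenotypeTable, pops: PopulationMap, n_perm: int = 1000,
           seed: int = 0) -> FstMatrix:
    """Pairwise multilocus Weir-Cockerham theta between all populations.

    Theta is the ratio of summed among-population variance components over
    loci.  Significance is assessed by permuting individuals between the two
    populations of each pair (+1 convention).
    """
    rng = np.random.default_rng(seed)
    labels = pops.labels()
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    by_pop = _pop_genotypes(table, pops)
    for p in labels:
        if all(len(g) == 0 for g in by_pop[p]):
            raise ValueError(f"population {p!r} absent from table")
    theta = pd.DataFrame(0.0, index=labels, columns=labels)
    pval = pd.DataFrame(np.nan, index=labels, columns=labels)
    for ia, pa in enumerate(labels):
        for pb in labels[ia + 1:]:
            obs = _multilocus_theta(by_pop[pa], by_pop[pb])
            theta.loc[pa, pb] = theta.loc[pb, pa] = obs
            if n_perm > 0 and np.isfinite(obs):
                ge = 0
                merged = [np.concatenate([ga, gb], axis=0)
                          for ga, gb in zip(by_pop[pa], by_pop[pb])]
                sizes = [(len(ga), len(gb))
                         for ga, gb in zip(by_pop[pa], by_pop[pb])]
                for _ in range(n_perm):
                    ga_s, gb_s = [], []
                    for m, (na, _nb) in zip(merged, sizes):
                        perm = rng.permutation(len(m))
                        ga_s.append(m[perm[:na]])
                        gb_s.append(m[perm[na:]])
                    if _multilocus_theta(ga_s, gb_s) >= obs:
                        ge += 1
                p = (1 + ge) / (n_perm + 1)
                pval.loc[pa, pb] = pval.loc[pb, pa] = p
    return FstMatrix(theta=theta, pvalue=pval)


# ---------------------------------------------------------------------------
# Rarefied allelic richness and private-allele richness
# ---------------------------------------------------------------------------

def _absence_prob(N: int, Ni: int, g: int) -> float:
    """Probability that an allele with Ni copies is absent from a g-subsample."""
    if Ni == 0:
        return 1.0
    if N - Ni < g:
        return 0.0
    return math.comb(N - Ni, g) / math.comb(N, g)


def rarefied_richness(table: GenotypeTable, pops: PopulationMap, g: int):
    """Rarefied allelic richness A_r and private-allele richness A_p.

    For a standardized sample of ``g`` gene copies, ``A_r`` is the expected
    number of distinct alleles and ``A_p`` the expected number of alleles
    present in the focal population's g-sample but absent from independent
    g-samples of every other population.  Loci where any population has fewer
    than ``g`` scored gene copies are dropped with a warning.

    Returns ``(per_locus, averaged)``: a DataFrame indexed by (population,
    locus) and a DataFrame of per-population means.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    labels = pops.labels()
    by_pop = _pop_genotypes(table, pops)
    copies = {p: [g_.size * 2 for g_ in by_pop[p]] for p in labels}
    min_copies = min(min(v) for v in copies.values())
    if g > min_copies and all(
            any(copies[p][j] < g for p in labels) for j in range(table.n_loci)):
        raise ValueError(f"g={g} exceeds scored gene copies at every locus "
                         f"(min {min_copies})")
    kept = [j for j in range(table.n_loci)
            if all(copies[p][j] >= g for p in labels)]
    dropped = sorted(set(range(table.n_loci)) - set(kept))
    if dropped:
        warnings.warn(f"dropping loci with <{g} gene copies in some "
                      f"population: {[table.loci[j].name for j in dropped]}")

    rows = []
    for j in kept:
        # per-pop allele counts on the union of alleles at this locus
        union = np.unique(np.concatenate(
            [by_pop[p][j].ravel() for p in labels if by_pop[p][j].size]))
        counts = {}
        for p in labels:
            al = by_pop[p][j].ravel()
            ai = np.searchsorted(union, al)
            counts[p] = np.bincount(ai, minlength=union.size)
        Q = {p: np.array([_absence_prob(int(counts[p].sum()), int(ni), g)
                          for ni in counts[p]]) for p in labels}
        for p in labels:
            ar = float((1.0 - Q[p]).sum())
            others = [q for lab, q in Q.items() if lab != p]
            prod_absent = np.prod(others, axis=0) if others else np.ones(union.size)
            ap = float(((1.0 - Q[p]) * prod_absent).sum())
            rows.append((p, table.loci[j].name, ar, ap))
    per_locus = pd.DataFrame(rows, columns=["population", "locus", "A_r", "A_p"]
                             ).set_index(["population", "locus"])
    averaged = per_locus.groupby(level="population").mean().loc[labels]
    return per_locus, averaged


# ---------------------------------------------------------------------------
# Null alleles (Chakraborty estimator)
# ---------------------------------------------------------------------------

def null_allele_freq(table: GenotypeTable, pops: PopulationMap):
    """Per-locus, per-population null-allele proportion and population mean.

    Uses the heterozygote-deficit estimator ``r = (H_E - H_O) / (H_E + H_O)``
    floored at zero; monomorphic loci are 0 by convention.
    """
    labels = pops.labels()
    by_pop = _pop_genotypes(table, pops)
    per_locus = pd.DataFrame(0.0, index=[l.name for l in table.loci],
                             columns=labels)
    for p in labels:
        for j, g in enumerate(by_pop[p]):
            he = nei_unbiased_diversity(g.ravel()) if g.size else 0.0
            if not np.isfinite(he) or he == 0:
                r = 0.0
            else:
                ho = observed_heterozygosity(g)
                r = max(0.0, (he - ho) / (he + ho))
            per_locus.iloc[j, per_locus.columns.get_loc(p)] = r
    mean = per_locus.mean(axis=0).rename("P_NA")
    return per_locus, mean


# ---------------------------------------------------------------------------
# Lynch & Ritland (1999) relatedness
# ---------------------------------------------------------------------------

def allele_frequencies(table: GenotypeTable,
                       ref_individuals: list[str] | None = None):
    """Per-locus allele frequency dictionaries from a reference set.

    Defaults to all individuals in the table; missing calls are excluded.
    """
    if ref_individuals is None:
        rows = np.arange(table.n_individuals)
    else:
        pos = {ind: i for i, ind in enumerate(table.individuals)}
        rows = np.array([pos[i] for i in ref_individuals], dtype=int)
    freqs = []
    for j in range(table.n_loci):
        a = table.calls[rows, j, :].ravel()
        a = a[a != MISSING]
        if a.size == 0:
            freqs.append({})
            continue
        al, ct = np.unique(a, return_counts=True)
        freqs.append(dict(zip(al.tolist(), (ct / a.size).tolist())))
    return freqs


def _lr_directed(gx, gy, freqs):
    """Directed Lynch-Ritland estimate with x as reference individual.

    Returns (weighted numerator, weight) sums over usable loci; loci missing in
    either individual, with a zero-frequency reference allele, or with a
    degenerate denominator are skipped.
    """
    num_sum = w_sum = 0.0
    used = 0
    for j, f in enumerate(freqs):
        a, b = int(gx[j, 0]), int(gx[j, 1])
        c, d = int(gy[j, 0]), int(gy[j, 1])
        if a == MISSING or c == MISSING or not f:
            continue
        pa = f.get(a, 0.0)
        pb = f.get(b, 0.0)
        if pa == 0.0 or pb == 0.0:
            continue
        dab = 1.0 if a == b else 0.0
        num = (pa * ((b == c) + (b == d)) + pb * ((a == c) + (a == d))
               - 4 * pa * pb)
        den = (1 + dab) * (pa + pb) - 4 * pa * pb
        if den <= 0:
            continue
        w = den / (2 * pa * pb)
        # weighted mean of per-locus r = num/den with weight w
        num_sum += w * (num / den)
        w_sum += w
        used += 1
    if used == 0 or w_sum == 0:
        return np.nan
    return num_sum / w_sum


def rxy_pairs(table: GenotypeTable, pairs, freqs=None) -> np.ndarray:
    """Symmetrized Lynch-Ritland relatedness for an iterable of index pairs."""
    if freqs is None:
        freqs = allele_frequencies(table)
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        gx, gy = table.calls[i], table.calls[j]
        r1 = _lr_directed(gx, gy, freqs)
        r2 = _lr_directed(gy, gx, freqs)
        out[k] = np.nanmean([r1, r2])
    return out


def rxy_matrix(table: GenotypeTable,
               ref_individuals: list[str] | None = None) -> pd.DataFrame:
    """Symmetric pairwise relatedness matrix (mean of the two directed estimates).

    Reference allele frequencies default to all individuals in the table.
    """
    freqs = allele_frequencies(table, ref_individuals)
    n = table.n_individuals
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    vals = rxy_pairs(table, pairs, freqs)
    m = np.zeros((n, n))
    for (i, j), v in zip(pairs, vals):
        m[i, j] = m[j, i] = v
    return pd.DataFrame(m, index=table.individuals, columns=table.individuals)


# ---------------------------------------------------------------------------
# Gaussian check on the relatedness distribution
# ---------------------------------------------------------------------------

def gaussian_relatedness_test(rxy_values, n_bins: int = 20,
                              n_sim: int = 10000, seed: int = 0):
    """Compare the r_xy distribution to Normal(0, observed sd).

    A Gaussian sample of equal size (mean 0, sd equal to the sample sd of the
    input) is simulated; both samples are binned on common quantile-based
    edges and the resulting 2 x n_bins contingency table is tested -- with
    Fisher's exact test when the table is 2 x 2, otherwise with a Monte-Carlo
    permutation test on the chi-square statistic.  Returns ``(p_value, sd)``.
    """
    x = np.asarray(rxy_values, dtype=float)
    if x.size < 30:
        raise ValueError("need at least 30 relatedness values")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("degenerate (zero-variance) input")
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, sd, size=x.size)
    pooled = np.concatenate([x, y])
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    edges[0], edges[-1] = -np.inf, np.inf
    cx = np.histogram(x, bins=edges)[0]
    cy = np.histogram(y, bins=edges)[0]
    tab = np.vstack([cx, cy])
    tab = tab[:, tab.sum(axis=0) > 0]
    if tab.shape[1] < 2:
        return 1.0, sd
    if tab.shape[1] == 2:
        from scipy.stats import fisher_exact
        return float(fisher_exact(tab)[1]), sd

    def chi2_stat(c1, margins, n1, ntot):
        exp1 = margins * (n1 / ntot)
        exp2 = margins - exp1
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(exp1 > 0, (c1 - exp1) ** 2 / exp1, 0.0) \
                + np.where(exp2 > 0, ((margins - c1) - exp2) ** 2 / exp2, 0.0)
        return s.sum(axis=-1)

    margins = tab.sum(axis=0)
    n1, ntot = tab[0].sum(), tab.sum()
    obs = chi2_stat(tab[0].astype(float), margins, n1, ntot)
    # permutation null with fixed margins: sequential hypergeometric sampling
    sims = np.empty((n_sim, margins.size))
    remaining_n1 = np.full(n_sim, n1)
    remaining = ntot
    for b, m in enumerate(margins):
        draw = rng.hypergeometric(remaining_n1, remaining - remaining_n1, m)
        sims[:, b] = draw
        remaining_n1 = remaining_n1 - draw
        remaining -= m
    null = chi2_stat(sims, margins, n1, ntot)
    p = (1 + int((null >= obs - 1e-12).sum())) / (n_sim + 1)
    return float(p), sd


# ---------------------------------------------------------------------------
# Ewens-Watterson neutrality test
# ---------------------------------------------------------------------------

def _ewens_expected_k(theta: float, n: int) -> float:
    i = np.arange(n)
    return float((theta / (theta + i)).sum())


def _theta_for_k(n: int, k: int) -> float:
    lo, hi = 1e-9, 1e9
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if _ewens_expected_k(mid, n) < k:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def _urn_homozygosity(n: int, theta: float, reps: int, rng) -> np.ndarray:
    """Homozygosity F and allele count K for ``reps`` Ewens (Hoppe-urn) samples.

    Vectorized across replicates: at each seating step a new allele appears
    with probability theta/(theta+i), otherwise an existing allele is chosen
    proportionally to its current count.
    """
    kmax_alloc = n
    counts = np.zeros((reps, min(kmax_alloc, 8)), dtype=np.int32)
    counts[:, 0] = 1
    k = np.ones(reps, dtype=np.int32)
    cur_k = 1
    for i in range(1, n):
        new = rng.random(reps) < theta / (theta + i)
        if new.any():
            if cur_k + 1 > counts.shape[1]:
                counts = np.pad(counts, ((0, 0), (0, 8)))
            counts[new, k[new]] = 1
            k[new] += 1
            cur_k = max(cur_k, int(k.max()))
        old = ~new
        if old.any():
            u = rng.random(old.sum()) * i
            cum = np.cumsum(counts[old, :cur_k], axis=1)
            idx = (cum > u[:, None]).argmax(axis=1)
            rows = np.flatnonzero(old)
            counts[rows, idx] += 1
    p = counts / n
    F = (p ** 2).sum(axis=1)
    return F, k


def ewens_watterson_test(allele_counts, n_sim: int = 10000, seed: int = 0):
    """Two-sided Ewens-Watterson homozygosity test per locus.

    ``allele_counts`` is a sequence of per-locus allele-count vectors.  The
    null distribution of ``F = sum p_i^2`` is sampled from the Ewens sampling
    distribution conditional on (n, k): Hoppe-urn replicates at a theta tuned
    so E[K] = k, retained by rejection on K = k.  The p-value is twice the
    smaller tail probability (capped at 1, +1 convention).
    """
    rng = np.random.default_rng(seed)
    pvals = []
    cache: dict[tuple[int, int], np.ndarray] = {}
    for counts in allele_counts:
        counts = np.asarray(counts, dtype=int)
        n = int(counts.sum())
        k = counts.size
        if n < 2:
            raise ValueError("need at least 2 gene copies")
        if k > n:
            raise ValueError("more alleles than gene copies")
        if k == 1:
            pvals.append(1.0)
            continue
        f_obs = float(((counts / n) ** 2).sum())
        key = (n, k)
        if key not in cache:
            theta = _theta_for_k(n, k)
            kept = []
            total = 0
            batch = max(n_sim, 2000)
            while total < n_sim and sum(len(x) for x in kept) < n_sim:
                F, K = _urn_homozygosity(n, theta, batch, rng)
                kept.append(F[K == k])
                total += batch
                if total > 50 * n_sim:
                    break
            null = np.concatenate(kept) if kept else np.array([])
            if null.size < 50:
                raise RuntimeError(
                    f"could not condition on k={k} alleles at n={n}")
            cache[key] = null
        null = cache[key]
        lo = (1 + int((null <= f_obs + 1e-12).sum())) / (null.size + 1)
        hi = (1 + int((null >= f_obs - 1e-12).sum())) / (null.size + 1)
        pvals.append(min(1.0, 2 * min(lo, hi)))
    return np.asarray(pvals)


# ---------------------------------------------------------------------------
# Clonal assignment
# ---------------------------------------------------------------------------

@dataclass
class ClonalPartition:
    """Single-linkage clonal lineages at a mismatch-distance threshold."""

    lineage: dict[str, int]
    threshold: int

    def groups(self):
        """Lineages as a set of frozensets of individual ids (order-free)."""
        out: dict[int, set] = {}
        for ind, g in self.lineage.items():
            out.setdefault(g, set()).add(ind)
        return {frozenset(v) for v in out.values()}


def pairwise_allele_distance(table: GenotypeTable) -> np.ndarray:
    """Pairwise count of allele mismatches over the 2L sorted allele slots.

    Genotypes are compared with alleles sorted within each locus; a locus
    missing in either individual contributes 0 differences.
    """
    calls = np.sort(table.calls, axis=2)
    n = table.n_individuals
    present = calls[:, :, 0] != MISSING
    both = present[:, None, :] & present[None, :, :]
    mism = (calls[:, None, :, :] != calls[None, :, :, :]).sum(axis=3)
    D = (mism * both).sum(axis=2)
    np.fill_diagonal(D, 0)
    return D


def assign_clones(table: GenotypeTable, threshold: int) -> ClonalPartition:
    """Partition individuals into single-linkage components at distance <= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    D = pairwise_allele_distance(table)
    adj = csr_matrix(D <= threshold)
    _, labels = connected_components(adj, directed=False)
    # canonical lineage ids by first occurrence
    remap: dict[int, int] = {}
    lineage = {}
    for ind, lab in zip(table.individuals, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        lineage[ind] = remap[lab]
    return ClonalPartition(lineage=lineage, threshold=threshold)


def min_merge_threshold(table: GenotypeTable) -> int:
    """Smallest pairwise mismatch distance in the table.

    The smallest threshold at which any two individuals would be merged into
    one clonal lineage.
    """
    D = pairwise_allele_distance(table)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    iu = np.triu_indices(n, k=1)
    return int(D[iu].min())
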