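"""Independent brute-force oracles for estimator tests.

Everything here is written directly from textbook definitions, deliberately
not sharing code with the package: plain loops, exhaustive enumeration over
subsamples, and exact probability formulas at tiny sizes.
"""

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components, direct transcription
# ---------------------------------------------------------------------------

def wc_components(genotypes_by_pop):
    """Summed (a, b, c) over alleles for one locus.

    ``genotypes_by_pop``: list of lists of (allele1, allele2) tuples.
    """
    pops = [p for p in genotypes_by_pop if len(p) > 0]
    r = len(pops)
    alleles = sorted({a for p in pops for g in p for a in g})
    n = [len(p) for p in pops]
    nbar = sum(n) / r
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p_i, h_i = [], []
        for pop in pops:
            copies = sum(int(g[0] == al) + int(g[1] == al) for g in pop)
            p_i.append(copies / (2 * len(pop)))
            h_i.append(sum(1 for g in pop
                           if g[0] != g[1] and al in g) / len(pop))
        pbar = sum(ni * pi for ni, pi in zip(n, p_i)) / sum(n)
        hbar = sum(ni * hi for ni, hi in zip(n, h_i)) / sum(n)
        if r > 1:
            nc = (sum(n) - sum(ni ** 2 for ni in n) / sum(n)) / (r - 1)
            s2 = sum(ni * (pi - pbar) ** 2
                     for ni, pi in zip(n, p_i)) / ((r - 1) * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
        else:
            a = 0.0
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def fis_multilocus(per_locus_genotypes):
    """Multilocus F_IS = 1 - sum(c)/sum(b + c) for a single population."""
    b_tot = c_tot = 0.0
    for genos in per_locus_genotypes:
        if len({a for g in genos for a in g}) < 2:
            continue
        _, b, c = wc_components([genos])
        b_tot += b
        c_tot += c
    if b_tot + c_tot == 0:
        return float("nan")
    return 1.0 - c_tot / (b_tot + c_tot)


def theta_multilocus(per_locus_pair):
    """Multilocus pairwise theta = sum(a)/sum(a+b+c) over loci."""
    a_tot = d_tot = 0.0
    for genos_a, genos_b in per_locus_pair:
        if len({al for g in genos_a + genos_b for al in g}) < 2:
            continue
        a, b, c = wc_components([genos_a, genos_b])
        a_tot += a
        d_tot += a + b + c
    if d_tot == 0:
        return float("nan")
    return a_tot / d_tot


# ---------------------------------------------------------------------------
# Rarefaction by exhaustive enumeration over all C(N, g) subsamples
# ---------------------------------------------------------------------------

def exhaustive_richness(pop_copies, g):
    """(A_r per pop, A_p per pop) for one locus by full enumeration.

    ``pop_copies``: list (per population) of lists of allele labels (gene
    copies).  A_r is the average number of distinct alleles over all g-sized
    subsamples.  A_p averages, over independent subsamples of every
    population, the number of alleles seen in the focal sample and in no
    other population's sample.
    """
    P = len(pop_copies)
    subsets = [list(itertools.combinations(copies, g))
               for copies in pop_copies]
    a_r = [float(np.mean([len(set(s)) for s in subs])) for subs in subsets]
    a_p = []
    for focal in range(P):
        total = 0.0
        count = 0
        for combo in itertools.product(*subsets):
            others = set()
            for j, s in enumerate(combo):
                if j != focal:
                    others.update(s)
            total += len(set(combo[focal]) - others)
            count += 1
        a_p.append(total / count)
    return a_r, a_p


# ---------------------------------------------------------------------------
# Ewens sampling formula, exact conditional on k at tiny n
# ---------------------------------------------------------------------------

def _partitions(n, k, max_part=None):
    """All integer partitions of n into exactly k parts (non-increasing)."""
    if max_part is None:
        max_part = n
    if k == 1:
        if n <= max_part:
            yield (n,)
        return
    for first in range(min(n - k + 1, max_part), 0, -1):
        for rest in _partitions(n - first, k - 1, first):
            yield (first,) + rest


def ewens_conditional_f(n, k):
    """Exact conditional distribution of homozygosity F given (n, k).

    Under the Ewens sampling formula, conditional on the number of alleles k
    the allele-count partition probability is proportional to
    n! / (prod_j parts_j * prod_m a_m!) where a_m is the multiplicity of part
    size m (theta cancels).  Returns {F_value: probability}.
    """
    weights = {}
    for part in _partitions(n, k):
        mult = {}
        for x in part:
            mult[x] = mult.get(x, 0) + 1
        w = math.factorial(n)
        for x in part:
            w /= x
        for m in mult.values():
            w /= math.factorial(m)
        f = sum((x / n) ** 2 for x in part)
        weights[f] = weights.get(f, 0.0) + w
    tot = sum(weights.values())
    return {f: w / tot for f, w in weights.items()}


def ewens_two_sided_p(n, k, f_obs):
    """Exact two-sided tail probability of F under the conditional ESF."""
    dist = ewens_conditional_f(n, k)
    lo = sum(p for f, p in dist.items() if f <= f_obs + 1e-12)
    hi = sum(p for f, p in dist.items() if f >= f_obs - 1e-12)
    return min(1.0, 2 * min(lo, hi))


# ---------------------------------------------------------------------------
# Graph oracles
# ---------------------------------------------------------------------------

def brute_force_components(dist, threshold):
    """Connected components of the <=threshold graph by flood fill."""
    n = len(dist)
    seen = [False] * n
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], set()
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.add(u)
            for v in range(n):
                if not seen[v] and dist[u][v] <= threshold:
                    seen[v] = True
                    stack.append(v)
        comps.append(frozenset(comp))
    return set(comps)


def allele_mismatch(g1, g2):
    """Sorted-pair allele mismatch distance between two multilocus genotypes."""
    d = 0
    for (a1, a2), (b1, b2) in zip(g1, g2):
        if -1 in (a1, a2, b1, b2):
            continue
        x, y = sorted((a1, a2)), sorted((b1, b2))
        d += (x[0] != y[0]) + (x[1] != y[1])
    return d
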