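"""Study-like synthetic microsatellite datasets with a planted-feature truth record.

The generator emulates the structure of a multi-species *Malus* survey —
five populations with realistic sample sizes, 26 loci, high gene diversity,
and a realistic non-star pairwise F_ST pattern — by drawing per-species allele
frequencies from a hierarchical Balding-Nichols model around a common
ancestral frequency vector, calibrated by an iterative rescaling of the
per-species drift parameters until the realized Weir-Cockerham F_ST of the
generated genotypes is close to each target.  On top of the base dataset it
plants known admixed individuals, misclassified individuals, full-sib pairs,
near-clone pairs, null alleles and missing data, and records every planted
feature so screening and clonal-assignment operations can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent_sim import (DatasetMutationParams, MutationHyperparams,
                             build_scenario, default_abc_loci,
                             draw_locus_params, simulate_dataset)
from .abc_inference import ObservedStats, summary_stats
from .genotype_io import MISSING, GenotypeTable, LocusDef, PopulationMap
from .popgen_stats import wc_fst

__all__ = ["StudyEmulationConfig", "TruthRecord", "make_study_like",
           "PodResult", "make_pods", "DEFAULT_TARGET_FST"]

#: Default pairwise F_ST targets for the five-species survey emulation.
DEFAULT_TARGET_FST = {
    ("bacc", "sylv"): 0.1683, ("bacc", "dom"): 0.1505,
    ("bacc", "siev"): 0.1457, ("bacc", "ori"): 0.1337,
    ("sylv", "dom"): 0.0056, ("sylv", "siev"): 0.0818,
    ("sylv", "ori"): 0.0579, ("dom", "siev"): 0.0639,
    ("dom", "ori"): 0.0494, ("siev", "ori"): 0.0393,
}

DEFAULT_SIZES = {"dom": 299, "ori": 215, "siev": 168, "sylv": 40, "bacc": 48}


@dataclass
class StudyEmulationConfig:
    """Knobs of the study-like generator (defaults emulate the survey)."""

    sample_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SIZES))
    n_loci: int = 26
    n_alleles: int = 12
    target_fst: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_FST))
    admixed_frac: float = 0.0        # fraction of dom individuals with a wild gamete
    n_misclassified: int = 0         # wild-labelled individuals with pure dom genotype
    n_sib_pairs: int = 0
    n_clone_pairs: int = 0
    clone_distance: int = 3          # allele slots mutated within a clone pair
    null_allele_freq: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    fst_rel_tol: float = 0.25
    max_calibration_iter: int = 80
    seed: int = 0

    def __post_init__(self):
        for nm, v in (("admixed_frac", self.admixed_frac),
                      ("missing_rate", self.missing_rate)):
            if not 0 <= v <= 1:
                raise ValueError(f"{nm} must be in [0, 1]")
        for s, n in self.sample_sizes.items():
            if n < 2:
                raise ValueError(f"population {s!r} needs >= 2 individuals")
        for pair, t in self.target_fst.items():
            if t > 0.5:
                raise ValueError(f"F_ST target {t} for {pair} infeasible "
                                 "with high-diversity loci")


@dataclass
class TruthRecord:
    """Every feature planted by :func:`make_study_like`."""

    membership: pd.DataFrame            # true ancestry proportions
    home: dict[str, str]                # labelled species per individual
    admixed: dict[str, str]             # individual -> donor species
    misclassified: dict[str, str]       # individual -> true source species
    sib_pairs: list[tuple[str, str]]
    clone_pairs: list[tuple[str, str, int]]
    null_loci: dict[str, float]
    target_fst: dict[tuple[str, str], float]
    realized_fst: pd.DataFrame
    species_freqs: np.ndarray           # (n_species, n_loci, n_alleles)
    drift: dict[str, float]


class _DriftTree:
    """UPGMA tree over the species with per-edge drift coefficients.

    Pairwise F_ST is approximately additive along tree paths for small drift,
    so per-edge drift is initialised from the UPGMA branch lengths of the
    target matrix and then rescaled multiplicatively against the realized
    values.  A star phylogeny cannot reproduce the survey pattern (dom and
    sylv nearly undifferentiated while both are far from bacc); the tree can.
    """

    def __init__(self, species, targets):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        self.species = list(species)
        S = len(self.species)
        D = np.zeros((S, S))
        default = float(np.mean(list(targets.values()))) if targets else 0.05
        for i in range(S):
            for j in range(i + 1, S):
                key = (self.species[i], self.species[j])
                rkey = key[::-1]
                D[i, j] = D[j, i] = targets.get(key, targets.get(rkey, default))
        if S == 2:
            merges = np.array([[0, 1, D[0, 1], 2]])
        else:
            merges = average(squareform(D, checks=False))
        self.parent: dict[int, int] = {}
        height = {i: 0.0 for i in range(S)}
        for m, (a, b, h, _cnt) in enumerate(merges):
            node = S + m
            self.parent[int(a)] = node
            self.parent[int(b)] = node
            height[node] = h / 2.0
        self.height = height
        self.root = S + len(merges) - 1
        self.drift = {c: max(height[p] - height[c], 1e-4)
                      for c, p in self.parent.items()}

    def _edge_chain(self, leaf):
        """Edges (keyed by child node) from a leaf up to the root."""
        chain = []
        n = leaf
        while n in self.parent:
            chain.append(n)
            n = self.parent[n]
        return chain

    def _path_edges(self, i, j):
        """Edges on the tree path between two leaves (symmetric difference)."""
        return set(self._edge_chain(i)) ^ set(self._edge_chain(j))

    def rescale(self, ratios_by_pair, damp=0.5):
        """Multiplicatively update edge drift from target/realized ratios."""
        per_edge: dict[int, list[float]] = {}
        for (i, j), ratio in ratios_by_pair.items():
            for e in self._path_edges(i, j):
                per_edge.setdefault(e, []).append(ratio)
        for e, rs in per_edge.items():
            gm = float(np.exp(np.mean(np.log(rs))))
            self.drift[e] = float(np.clip(self.drift[e] * gm ** damp,
                                          1e-5, 0.9))

    def draw_freqs(self, rng, n_loci, n_alleles):
        """Species allele frequencies by cascading Balding-Nichols draws."""
        S = len(self.species)
        order = sorted(self.height, key=lambda n: -self.height[n])
        freqs = np.empty((S, n_loci, n_alleles))
        for j in range(n_loci):
            node_freq = {self.root: rng.dirichlet(np.full(n_alleles, 2.0))}
            for node in order:
                if node == self.root:
                    continue
                pf = node_freq[self.parent[node]]
                F = self.drift[node]
                node_freq[node] = rng.dirichlet(
                    np.maximum(pf, 1e-9) * (1 - F) / F)
            for si in range(S):
                freqs[si, j] = node_freq[si]
        return freqs


def _sample_genotypes(rng, freq_pop, n_ind, allele_lengths):
    """(n_ind, n_loci, 2) genotypes drawn in Hardy-Weinberg proportions."""
    n_loci, n_alleles = freq_pop.shape
    calls = np.empty((n_ind, n_loci, 2), dtype=np.int32)
    for j in range(n_loci):
        idx = rng.choice(n_alleles, size=(n_ind, 2), p=freq_pop[j])
        calls[:, j, :] = allele_lengths[idx]
    return calls


def make_study_like(config: StudyEmulationConfig):
    """Generate a study-like dataset.

    Returns ``(GenotypeTable, PopulationMap, TruthRecord)``.  The F_ST
    calibration loop redraws species frequencies, rescaling the per-species
    drift parameters, until the realized Weir-Cockerham estimates on the
    generated genotypes are within ``fst_rel_tol`` (relative) of every target.
    """
    rng = np.random.default_rng(config.seed)
    species = list(config.sample_sizes)
    loci = [LocusDef(f"L{j:02d}", motif_len=2, n_states=40, min_len=100)
            for j in range(config.n_loci)]
    allele_lengths = np.array([100 + 2 * a for a in range(config.n_alleles)],
                              dtype=np.int32)
    targets = {p: t for p, t in config.target_fst.items()
               if p[0] in species and p[1] in species}
    tree = _DriftTree(species, targets)

    individuals, home = [], {}
    for s in species:
        for i in range(config.sample_sizes[s]):
            ind = f"{s}_{i:04d}"
            individuals.append(ind)
            home[ind] = s
    pops = PopulationMap(dict(home))
    rows_of = {s: [i for i, ind in enumerate(individuals) if home[ind] == s]
               for s in species}

    # --- calibration loop on realized WC F_ST -----------------------------
    freqs = None
    calls = None
    realized = None
    for it in range(config.max_calibration_iter):
        freqs = tree.draw_freqs(rng, config.n_loci, config.n_alleles)
        calls = np.empty((len(individuals), config.n_loci, 2), dtype=np.int32)
        for si, s in enumerate(species):
            calls[rows_of[s]] = _sample_genotypes(
                rng, freqs[si], config.sample_sizes[s], allele_lengths)
        table = GenotypeTable(list(individuals), loci, calls)
        realized = wc_fst(table, pops, n_perm=0).theta
        ok = True
        ratios = {}
        for (s, t), tgt in targets.items():
            got = float(realized.loc[s, t])
            if abs(got - tgt) / tgt > config.fst_rel_tol:
                ok = False
            ratios[(species.index(s), species.index(t))] = \
                tgt / max(got, 1e-5)
        if ok:
            break
        tree.rescale(ratios)
    else:
        raise RuntimeError(
            "F_ST calibration did not converge; infeasible target pattern")

    # --- plant features ----------------------------------------------------
    membership = pd.DataFrame(0.0, index=individuals, columns=species)
    for ind in individuals:
        membership.loc[ind, home[ind]] = 1.0

    admixed: dict[str, str] = {}
    misclassified: dict[str, str] = {}
    sib_pairs: list[tuple[str, str]] = []
    clone_pairs: list[tuple[str, str, int]] = []
    protected = set()

    dom_rows = rows_of.get("dom", rows_of[species[0]])
    dom_sp = "dom" if "dom" in species else species[0]
    dom_si = species.index(dom_sp)
    wild = [s for s in species if s != dom_sp]

    n_adm = int(round(config.admixed_frac * len(dom_rows)))
    cursor = 0
    for k in range(n_adm):
        i = dom_rows[cursor]
        cursor += 1
        donor = wild[k % len(wild)]
        di = species.index(donor)
        # one gamete from home, one from the donor genepool
        for j in range(config.n_loci):
            a_home = allele_lengths[rng.choice(config.n_alleles,
                                               p=freqs[dom_si, j])]
            a_don = allele_lengths[rng.choice(config.n_alleles,
                                              p=freqs[di, j])]
            calls[i, j] = (a_home, a_don)
        ind = individuals[i]
        admixed[ind] = donor
        membership.loc[ind] = 0.0
        membership.loc[ind, dom_sp] = 0.5
        membership.loc[ind, donor] = 0.5
        protected.add(i)

    for k in range(config.n_misclassified):
        s = wild[k % len(wild)]
        i = rows_of[s][-(k // len(wild) + 1)]
        calls[i] = _sample_genotypes(rng, freqs[dom_si], 1, allele_lengths)[0]
        ind = individuals[i]
        misclassified[ind] = dom_sp
        membership.loc[ind] = 0.0
        membership.loc[ind, dom_sp] = 1.0
        protected.add(i)

    for k in range(config.n_sib_pairs):
        i1 = dom_rows[cursor]
        i2 = dom_rows[cursor + 1]
        cursor += 2
        par1 = _sample_genotypes(rng, freqs[dom_si], 1, allele_lengths)[0]
        par2 = _sample_genotypes(rng, freqs[dom_si], 1, allele_lengths)[0]
        for tgt_row in (i1, i2):
            for j in range(config.n_loci):
                calls[tgt_row, j] = (par1[j, rng.integers(2)],
                                     par2[j, rng.integers(2)])
        sib_pairs.append((individuals[i1], individuals[i2]))
        protected.update((i1, i2))

    for k in range(config.n_clone_pairs):
        i1 = dom_rows[cursor]
        i2 = dom_rows[cursor + 1]
        cursor += 2
        calls[i2] = calls[i1].copy()
        # mutate clone_distance loci, each adding exactly one mismatch under
        # the sorted-allele-pair distance used by clonal assignment
        mut_loci = rng.choice(config.n_loci, size=config.clone_distance,
                              replace=False)
        for j in mut_loci:
            orig = np.sort(calls[i2, j])
            choices = []
            for slot in (0, 1):
                for c in allele_lengths:
                    cand = orig.copy()
                    cand[slot] = c
                    if np.sum(np.sort(cand) != orig) == 1:
                        choices.append(tuple(np.sort(cand)))
            calls[i2, j] = choices[rng.integers(len(choices))]
        clone_pairs.append((individuals[i1], individuals[i2],
                            config.clone_distance))
        protected.update((i1, i2))

    # --- null alleles and missing data (planted pairs are left untouched) --
    locus_index = {loc.name: j for j, loc in enumerate(loci)}
    for locus_name, f_null in config.null_allele_freq.items():
        j = locus_index[locus_name]
        for i in range(len(individuals)):
            if i in protected:
                continue
            nulls = rng.random(2) < f_null
            if nulls.all():
                calls[i, j] = (MISSING, MISSING)
            elif nulls.any():
                visible = calls[i, j, 1 - int(np.flatnonzero(nulls)[0])]
                calls[i, j] = (visible, visible)

    if config.missing_rate > 0:
        for i in range(len(individuals)):
            if i in protected:
                continue
            mask = rng.random(config.n_loci) < config.missing_rate
            calls[i, mask] = MISSING

    table = GenotypeTable(list(individuals), loci, calls)
    truth = TruthRecord(
        membership=membership, home=home, admixed=admixed,
        misclassified=misclassified, sib_pairs=sib_pairs,
        clone_pairs=clone_pairs, null_loci=dict(config.null_allele_freq),
        target_fst=targets, realized_fst=realized, species_freqs=freqs,
        drift={str(k): v for k, v in tree.drift.items()})
    return table, pops, truth


# ---------------------------------------------------------------------------
# Pseudo-observed datasets for validation experiments
# ---------------------------------------------------------------------------

@dataclass
class PodResult:
    """A pseudo-observed dataset with the parameters that generated it."""

    table: GenotypeTable
    pops: PopulationMap
    stats: ObservedStats
    params: dict


def make_pods(model_id: str, params: dict, samples: dict[str, int],
              n_loci: int = 14, seed: int = 1,
              admix_times: dict[str, float] | None = None) -> PodResult:
    """Simulate one pseudo-observed dataset under known parameters.

    ``params`` holds the demographic parameters (N1..N4, T1..T3, the model's
    admixture proportions) plus the dataset-level mutation means ``mu_mean``,
    ``p_mean`` and ``mu_sni_mean``; per-locus rates are drawn around them.
    """
    rng = np.random.default_rng(seed)
    demo_keys = ("N1", "N2", "N3", "N4", "T1", "T2", "T3")
    scen = build_scenario(
        model_id, **{k: float(params[k]) for k in demo_keys},
        **{k: float(v) for k, v in params.items()
           if k.startswith("r") and k != "r_bounds"},
        admix_times=admix_times)
    hyper = MutationHyperparams(
        mu_mean_bounds=(params["mu_mean"], params["mu_mean"]),
        p_mean_bounds=(params["p_mean"], params["p_mean"]),
        mu_sni_bounds=(params["mu_sni_mean"], params["mu_sni_mean"]))
    mut = draw_locus_params(hyper, default_abc_loci(n_loci), rng)
    table, pops = simulate_dataset(scen, mut, samples, n_loci=n_loci,
                                   seed=int(rng.integers(1, 2**31 - 1)))
    stats = summary_stats(table, pops, pop_order=list(samples))
    return PodResult(table=table, pops=pops, stats=stats, params=dict(params))
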