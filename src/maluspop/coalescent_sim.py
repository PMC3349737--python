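"""Coalescent simulation of microsatellites under divergence-with-admixture models.

Genealogies are generated with msprime under a structured coalescent in which
population splits and instantaneous admixture pulses are expressed as
(backward-time) lineage movements: at an admixture event each lineage in the
recipient population moves to the donor independently with probability ``r``;
at a split all lineages of the derived population move to the parent.

Mutations are overlaid on each genealogy as a Poisson process of rate
``mu_L + mu_SNI_L`` per lineage-generation.  Each event is, with probability
``mu_L / (mu_L + mu_SNI_L)``, a generalized stepwise (GSM) step changing the
allele length by ``motif_len * G`` nucleotides with ``G ~ Geometric(P_L)``
(support >= 1) and a fair sign, constrained to the locus's window of
contiguous lattice states by resampling steps that would exit; otherwise it is
a single-nucleotide indel of +-1 nt, unconstrained, which moves the allele off
the repeat lattice.  The root allele is the lattice midpoint (summary
statistics are translation invariant, so this choice is inert).

The four apple-domestication scenarios relate a domesticated population (dom,
derived from the Central Asian wild species siev) to two other wild species
(ori, sylv), with admixture pulses at fixed times of 600 (ori <-> dom),
200 (sylv <-> dom) and 13 (dom -> siev) generations before present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
from numba import njit

from .genotype_io import GenotypeTable, LocusDef, PopulationMap

__all__ = [
    "DemographicScenario", "MutationHyperparams", "LocusMutationParams",
    "DatasetMutationParams", "build_scenario", "panmictic_scenario",
    "draw_locus_params", "simulate_dataset", "simulate_genotype_arrays",
    "default_abc_loci", "DEFAULT_SAMPLES", "ADMIX_TIMES",
]

#: Diploid sample sizes of the study populations.
DEFAULT_SAMPLES = {"dom": 299, "ori": 215, "siev": 168, "sylv": 40}

#: Fixed admixture times (generations before present) used by the presets.
#: The alternative "recent sylv admixture" variant uses 67 instead of 200.
ADMIX_TIMES = {"ori": 600.0, "sylv": 200.0, "siev": 13.0}

#: The 14 perfect-repeat loci used for demographic inference.  Two loci have
#: wider allelic windows (44 and 42 contiguous states); the rest use 40.
_ABC_LOCUS_NAMES = [
    "Ch01h01", "Ch01h10", "Ch02c06", "Ch02d08", "Ch05f06", "Ch01f02",
    "Hi02c07", "Ch02c09", "Ch03d07", "Ch04c07", "Ch02b03b", "MS06g03",
    "Ch04e03", "Ch02g01",
]
_SPECIAL_STATES = {"Ch02c06": 44, "Ch04e03": 42}


def default_abc_loci(n_loci: int = 14, motif_len: int = 2) -> list[LocusDef]:
    """Locus definitions for the inference panel (cycled if n_loci > 14)."""
    loci = []
    for i in range(n_loci):
        name = _ABC_LOCUS_NAMES[i % len(_ABC_LOCUS_NAMES)]
        if i >= len(_ABC_LOCUS_NAMES):
            name = f"{name}_{i // len(_ABC_LOCUS_NAMES)}"
        loci.append(LocusDef(name=name, motif_len=motif_len,
                             n_states=_SPECIAL_STATES.get(name.split("_")[0], 40)))
    return loci


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------

@dataclass
class DemographicScenario:
    """Populations, split times and timed admixture pulses.

    ``populations`` maps name -> diploid effective size.  ``splits`` holds
    ``(time, derived, parent)`` tuples; ``admixtures`` holds ``(time,
    recipient, donor, proportion)`` tuples (forward-time reading: the
    recipient derives ``proportion`` of its genes from the donor at that
    time).  Ancestral lineages carry the parent population's size unless
    ``ancestral_sizes`` overrides it at a split.
    """

    populations: dict[str, float]
    splits: list[tuple[float, str, str]] = field(default_factory=list)
    admixtures: list[tuple[float, str, str, float]] = field(default_factory=list)
    model_id: str | None = None
    ancestral_sizes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, N in self.populations.items():
            if N <= 0:
                raise ValueError(f"population {name!r} has non-positive size")
        split_time = {d: t for t, d, _ in self.splits}
        for t, d, p in self.splits:
            if t <= 0:
                raise ValueError(f"split time of {d!r} must be positive")
            if p in split_time and split_time[p] <= t:
                raise ValueError(
                    f"population {p!r} splits before its derived {d!r}")
        for t, rec, don, r in self.admixtures:
            if not 0 <= r <= 1:
                raise ValueError(f"admixture proportion {r} outside [0, 1]")
            for pop in (rec, don):
                if pop in split_time and t >= split_time[pop]:
                    raise ValueError(
                        f"admixture at {t} involves {pop!r} which has already "
                        f"merged at {split_time[pop]} (constraint: admixture "
                        "time < split time of both populations)")

    def to_demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        for name, N in self.populations.items():
            dem.add_population(name=name, initial_size=N)
        events = []
        for seq, (t, rec, don, r) in enumerate(self.admixtures):
            events.append((t, 0, seq, ("admix", rec, don, r)))
        for seq, (t, d, p) in enumerate(self.splits):
            events.append((t, 1, seq, ("split", d, p)))
        for t, _, _, ev in sorted(events, key=lambda e: (e[0], e[1], e[2])):
            if ev[0] == "admix":
                _, rec, don, r = ev
                dem.add_mass_migration(time=t, source=rec, dest=don,
                                       proportion=r)
            else:
                _, d, p = ev
                dem.add_mass_migration(time=t, source=d, dest=p, proportion=1.0)
                if d in self.ancestral_sizes:
                    dem.add_population_parameters_change(
                        time=t, population=p,
                        initial_size=self.ancestral_sizes[d])
        return dem


def panmictic_scenario(N: float, name: str = "pop") -> DemographicScenario:
    """A single constant-size population (no structure, no events)."""
    return DemographicScenario(populations={name: N}, model_id=None)


def build_scenario(model_id: str, *, N1: float, N2: float, N3: float,
                   N4: float, T1: float, T2: float, T3: float,
                   r1: float = 0.0, r2: float = 0.0, r3: float = 0.0,
                   r4: float = 0.0, r5: float = 0.0,
                   admix_times: dict[str, float] | None = None
                   ) -> DemographicScenario:
    """One of the four divergence-with-admixture models (a-d).

    Populations: dom (size N1), ori (N2), siev (N3), sylv (N4).  Splits: dom
    from siev at T3, ori from siev at T2, sylv from siev at T1, with
    0 < T3 < T2 < T1.  Admixture pulses at fixed times (default 600 ori<->dom,
    200 sylv<->dom, 13 dom->siev):

    - model a: siev receives r1 from dom at 13; dom receives r2 from sylv and
      sylv receives r3 from dom at 200; ori receives r4 from dom and dom
      receives r5 from ori at 600;
    - model b: r2 (at 200) and r5 (at 600) only — no introgression from dom
      into the wild species;
    - model c: r2 only — a single pulse from sylv into dom;
    - model d: no admixture.
    """
    if model_id not in "abcd" or len(model_id) != 1:
        raise ValueError(f"unknown model id {model_id!r}")
    if not 0 < T3 < T2 < T1:
        raise ValueError(f"divergence times must satisfy 0 < T3 < T2 < T1 "
                         f"(got T3={T3}, T2={T2}, T1={T1})")
    at = dict(ADMIX_TIMES)
    if admix_times:
        at.update(admix_times)
    events = {
        "a": [(at["siev"], "siev", "dom", r1),
              (at["sylv"], "dom", "sylv", r2),
              (at["sylv"], "sylv", "dom", r3),
              (at["ori"], "ori", "dom", r4),
              (at["ori"], "dom", "ori", r5)],
        "b": [(at["sylv"], "dom", "sylv", r2),
              (at["ori"], "dom", "ori", r5)],
        "c": [(at["sylv"], "dom", "sylv", r2)],
        "d": [],
    }[model_id]
    return DemographicScenario(
        populations={"dom": N1, "ori": N2, "siev": N3, "sylv": N4},
        splits=[(T3, "dom", "siev"), (T2, "ori", "siev"), (T1, "sylv", "siev")],
        admixtures=events,
        model_id=model_id,
    )


# ---------------------------------------------------------------------------
# Mutation model
# ---------------------------------------------------------------------------

@dataclass
class MutationHyperparams:
    """Priors for the dataset-level mutation means and per-locus truncation.

    The dataset-level mean GSM rate is uniform on ``mu_mean_bounds``
    (default 1e-4..1e-3 per generation) and the mean geometric parameter is
    uniform on ``p_mean_bounds`` (default 0.1..0.3); the mean indel rate is
    log-uniform on ``mu_sni_bounds``.  Per-locus values are Gamma(shape 2,
    mean as drawn), resampled into the truncation intervals.
    """

    mu_mean_bounds: tuple[float, float] = (1e-4, 1e-3)
    p_mean_bounds: tuple[float, float] = (0.1, 0.3)
    mu_sni_bounds: tuple[float, float] = (1e-8, 1e-4)
    shape: float = 2.0
    mu_locus_bounds: tuple[float, float] = (5e-5, 5e-2)
    p_locus_bounds: tuple[float, float] = (0.01, 0.9)

    def __post_init__(self):
        for nm in ("mu_mean_bounds", "p_mean_bounds", "mu_sni_bounds",
                   "mu_locus_bounds", "p_locus_bounds"):
            lo, hi = getattr(self, nm)
            if not 0 < lo <= hi:
                raise ValueError(f"{nm} must be positive with lo <= hi")


@dataclass
class LocusMutationParams:
    """Realized per-locus mutation parameters on a locus definition."""

    locus: LocusDef
    mu: float          # GSM rate per generation
    p_geom: float      # geometric step-length parameter
    mu_sni: float      # single-nucleotide indel rate per generation

    def __post_init__(self):
        if self.mu < 0 or self.mu_sni < 0 or not 0 < self.p_geom <= 1:
            raise ValueError("invalid mutation parameters")


@dataclass
class DatasetMutationParams:
    """Dataset-level means plus the per-locus draws."""

    mu_mean: float
    p_mean: float
    mu_sni_mean: float
    per_locus: list[LocusMutationParams]


def _truncated_gamma(rng, shape, mean, lo, hi, max_rejections=10_000):
    scale = mean / shape
    for _ in range(max_rejections):
        x = rng.gamma(shape, scale)
        if lo <= x <= hi:
            return x
    raise RuntimeError(
        f"truncated Gamma(mean={mean}, shape={shape}) on [{lo}, {hi}]: "
        f"negligible mass (> {max_rejections} rejections)")


def draw_locus_params(hyper: MutationHyperparams, loci: list[LocusDef],
                      rng: np.random.Generator) -> DatasetMutationParams:
    """Draw dataset-level means and per-locus mutation parameters."""
    mu_mean = rng.uniform(*hyper.mu_mean_bounds)
    p_mean = rng.uniform(*hyper.p_mean_bounds)
    lo, hi = hyper.mu_sni_bounds
    mu_sni_mean = np.exp(rng.uniform(np.log(lo), np.log(hi)))
    per_locus = []
    for loc in loci:
        mu = _truncated_gamma(rng, hyper.shape, mu_mean, *hyper.mu_locus_bounds)
        p = _truncated_gamma(rng, hyper.shape, p_mean, *hyper.p_locus_bounds)
        sni = rng.gamma(hyper.shape, mu_sni_mean / hyper.shape)
        per_locus.append(LocusMutationParams(loc, mu, p, max(sni, 1e-300)))
    return DatasetMutationParams(mu_mean, p_mean, mu_sni_mean, per_locus)


# ---------------------------------------------------------------------------
# Mutation overlay kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _overlay_mutations(order, parent, times, mu, mu_sni, p_geom, motif,
                       lo, hi, root_state, seed):  # pragma: no cover - numba
    """Walk a genealogy in preorder applying GSM and indel mutations."""
    np.random.seed(seed)
    states = np.empty(parent.size, dtype=np.int64)
    total = mu + mu_sni
    p_gsm = 1.0 if total == 0.0 else mu / total
    for idx in range(order.size):
        u = order[idx]
        par = parent[u]
        if par == -1:
            states[u] = root_state
            continue
        s = states[par]
        if total > 0.0:
            n_mut = np.random.poisson(total * (times[par] - times[u]))
            for _ in range(n_mut):
                if np.random.random() < p_gsm:
                    # GSM step, resampled into the allelic window
                    for _try in range(1000):
                        g = 1 if p_geom >= 1.0 else np.random.geometric(p_geom)
                        step = motif * g
                        if np.random.random() < 0.5:
                            step = -step
                        ns = s + step
                        if lo <= ns <= hi:
                            s = ns
                            break
                else:
                    # single-nucleotide indel, off-lattice, unconstrained
                    if np.random.random() < 0.5:
                        s += 1
                    elif s > 1:
                        s -= 1
        states[u] = s
    return states


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def _resolve_params(params, n_loci, rng):
    if isinstance(params, MutationHyperparams):
        return draw_locus_params(params, default_abc_loci(n_loci), rng)
    if isinstance(params, DatasetMutationParams):
        return params
    if isinstance(params, (list, tuple)):
        return DatasetMutationParams(np.nan, np.nan, np.nan, list(params))
    raise TypeError("params must be MutationHyperparams, "
                    "DatasetMutationParams or a list of LocusMutationParams")


def simulate_genotype_arrays(scenario: DemographicScenario, params,
                             samples: dict[str, int], n_loci: int = 14,
                             seed: int = 1):
    """Simulate per-locus diploid genotype arrays grouped by population.

    Returns ``(arrays, mut_params)`` where ``arrays[j][pop]`` is an
    ``(n_diploids, 2)`` int array of allele lengths at locus ``j``.  This is
    the fast path used for ABC reference tables; :func:`simulate_dataset`
    wraps it into a :class:`GenotypeTable`.
    """
    rng = np.random.default_rng(seed)
    mut = _resolve_params(params, n_loci, rng)
    if len(mut.per_locus) < n_loci:
        raise ValueError("fewer locus parameter sets than n_loci")
    for pop, n in samples.items():
        if pop not in scenario.populations:
            raise ValueError(f"sampled population {pop!r} not in scenario")
        if n < 1:
            raise ValueError(f"need >= 1 diploid sample in {pop!r}")
    dem = scenario.to_demography()
    msp_seed = int(rng.integers(1, 2**31 - 1))
    reps = msprime.sim_ancestry(
        samples={p: n for p, n in samples.items()}, demography=dem, ploidy=2,
        num_replicates=n_loci, random_seed=msp_seed)

    pop_names = list(samples)
    pop_id = {p.name: i for i, p in enumerate(dem.populations)}
    arrays = []
    for j, ts in enumerate(reps):
        tree = ts.first()
        lp = mut.per_locus[j]
        loc = lp.locus
        root_state = loc.min_len + loc.motif_len * (loc.n_states // 2)
        states = _overlay_mutations(
            tree.preorder(), tree.parent_array, ts.nodes_time,
            lp.mu, lp.mu_sni, lp.p_geom, loc.motif_len,
            loc.min_len, loc.max_len, root_state,
            int(rng.integers(1, 2**31 - 1)))
        node_pop = ts.nodes_population
        sample_nodes = ts.samples()
        locus_out = {}
        for pop in pop_names:
            nodes = sample_nodes[node_pop[sample_nodes] == pop_id[pop]]
            # uniform random diploid pairing of gene copies within population
            nodes = rng.permutation(nodes)
            locus_out[pop] = states[nodes].reshape(-1, 2).astype(np.int32)
        arrays.append(locus_out)
    return arrays, mut


def simulate_dataset(scenario: DemographicScenario, params,
                     samples: dict[str, int] | None = None,
                     n_loci: int = 14, seed: int = 1):
    """Simulate a multilocus microsatellite dataset under a scenario.

    ``params`` may be a :class:`MutationHyperparams` (priors: the dataset-level
    means are drawn internally), a :class:`DatasetMutationParams`, or a list of
    :class:`LocusMutationParams`.  Returns ``(GenotypeTable, PopulationMap)``.
    """
    samples = dict(samples or DEFAULT_SAMPLES)
    arrays, mut = simulate_genotype_arrays(scenario, params, samples,
                                           n_loci, seed)
    pop_names = list(samples)
    individuals, labels = [], {}
    for pop in pop_names:
        for i in range(samples[pop]):
            ind = f"{pop}_{i:04d}"
            individuals.append(ind)
            labels[ind] = pop
    n_tot = len(individuals)
    calls = np.empty((n_tot, n_loci, 2), dtype=np.int32)
    for j in range(n_loci):
        row = 0
        for pop in pop_names:
            g = arrays[j][pop]
            calls[row:row + len(g), j, :] = g
            row += len(g)
    loci = [lp.locus for lp in mut.per_locus[:n_loci]]
    return GenotypeTable(individuals, loci, calls), PopulationMap(labels)
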