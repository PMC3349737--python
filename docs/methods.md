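# Methods

This note documents the models and estimators implemented in `maluspop`, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data experiments do and do not demonstrate.

## Genotype representation

Alleles are stored as fragment lengths in nucleotides, not repeat counts.
Microsatellite panels contain alleles that are not whole multiples of the
repeat motif (single-nucleotide indels in the flanking or repeat region), and
the mutation model below produces such alleles; a repeat-count representation
could not hold them. Repeat counts, where an estimator needs them (the
Goldstein (δμ)² distance), are derived as `(length − min_len) / motif_len`
and may be fractional. A genotype is missing at both allele slots or at
neither; half-missing calls are rejected at parse time. GENEPOP files are
read with 2- or 3-digit allele codes auto-detected and written with 3-digit
codes; the writer emits `POP <label>` block headers (a dialect extension) so
population labels survive a round trip. Because the format groups rows by
population, a table with interleaved populations round-trips as content, not
byte-for-byte row order.

## Survey statistics

**Heterozygosity.** H<sub>E</sub> is Nei's unbiased gene diversity
`n(1 − Σp²)/(n − 1)` over the `n` scored gene copies; H<sub>O</sub> is the
proportion of heterozygous scored individuals.

**F-statistics.** F<sub>IS</sub> and pairwise F<sub>ST</sub> are the
Weir & Cockerham (1984) variance-component estimators, combined over alleles
and loci by summing components (a ratio of sums, not a mean of ratios).
With a single population the among-population component vanishes and the
within/between-individual decomposition gives F<sub>IS</sub> = 1 − Σc/Σ(b+c).
Significance: F<sub>IS</sub> permutes gene copies among individuals within
the population (re-pairing them into pseudo-genotypes); F<sub>ST</sub>
permutes individuals between the two populations of a pair. Permutation
p-values use the +1 convention (the observed arrangement counts in both
numerator and denominator). Note the estimators are unbiased but not
positive: two samples from one pool give a slightly negative θ of order
1/n̄.

**Rarefaction.** For a standardized sample of `g` gene copies,
A<sub>r</sub> = Σ<sub>i</sub> [1 − C(N−N<sub>i</sub>, g)/C(N, g)] over
alleles, and A<sub>p</sub> multiplies each allele's presence probability in
the focal population by its absence probability in an independent g-sample
of every other population. Binomial ratios are computed from exact integer
binomials, so small cases match exhaustive enumeration to machine precision.
Loci with fewer than `g` scored copies in any population are dropped with a
warning. The survey default is g = 22 (and g = 12 for pruned data sets),
matching standardized sample sizes commonly used for such panels.

**Null alleles.** The per-locus null-allele proportion is the
heterozygote-deficit estimator r = (H<sub>E</sub> − H<sub>O</sub>) /
(H<sub>E</sub> + H<sub>O</sub>), floored at zero, 0 for monomorphic loci; a
population's P<sub>NA</sub> is the mean over loci. This formula-level
estimator replaces iterative maximum-likelihood null-allele machinery: it is
reproducible from the published summary quantities alone.

**Relatedness.** r<sub>xy</sub> is the Lynch & Ritland (1999) regression
estimator. For reference genotype (a,b) and proband (c,d) with reference
allele frequencies p:

r̂ = [p<sub>a</sub>(δ<sub>bc</sub>+δ<sub>bd</sub>) +
p<sub>b</sub>(δ<sub>ac</sub>+δ<sub>ad</sub>) − 4p<sub>a</sub>p<sub>b</sub>] /
[(1+δ<sub>ab</sub>)(p<sub>a</sub>+p<sub>b</sub>) − 4p<sub>a</sub>p<sub>b</sub>]

Loci are combined with the published weights (the denominator over
2p<sub>a</sub>p<sub>b</sub>), and the two directed estimates are averaged
because the estimator is asymmetric and no direction is privileged in a
survey. Reference frequencies default to all individuals in the table. Loci
missing in either individual, with a zero-frequency reference allele, or
with a degenerate denominator are skipped for that pair. Calibration on
simulated pedigrees at 26 loci with eight equifrequent alleles gives means
of 0.50 (parent–offspring), 0.00 (unrelated) and > 0.9 (clones).

**Gaussian check on r<sub>xy</sub>.** The observed values are compared with
a simulated Normal(0, s) sample of equal size (s = observed sd) on common
quantile-based bin edges; the 2×k table is tested by Fisher's exact test
when it is 2×2 and otherwise by a Monte-Carlo permutation test on the
chi-square statistic, sampling null tables with fixed margins by sequential
hypergeometric draws. The binning is a documented convention — the
underlying comparison is only specified up to "observed versus simulated
distributions".

**Ewens–Watterson.** The observed homozygosity F = Σp² is referred to the
Ewens sampling distribution conditional on (n, k): Hoppe-urn replicates at a
θ tuned by bisection so E[K] = k, retained by rejection on K = k, with the
two-sided p-value twice the smaller tail (capped at 1). Exact enumeration
over partitions validates the sampler at tiny n.

**Clonal assignment.** The distance between two multilocus genotypes is the
number of mismatching allele slots with alleles sorted within each locus; a
locus missing in either individual contributes 0 (an optimistic reading that
makes the threshold an upper bound on observed differences). Lineages are
single-linkage components of the ≤-threshold graph; `min_merge_threshold`
reports the smallest pairwise distance, i.e. the smallest threshold at which
any two samples would be called the same genet. Pruning of related pairs
removes, repeatedly, the highest-degree vertex of the r<sub>xy</sub> ≥
threshold graph, breaking ties toward the later individual; the paper trail
for this choice is that it attains the minimum vertex cover on the simple
configurations that occur in practice (isolated pairs and stars).

## Bottleneck test

For each polymorphic locus, the gene diversity expected at mutation-drift
equilibrium given the observed allele count k and gene count n is estimated
by conditional coalescent simulation: single-population Kingman genealogies
(coalescence rate k(k−1)/4N per generation), stepwise mutations overlaid at
a rate tuned by bisection on θ so that E[K] ≈ k, and replicates retained
when K = k exactly. Under the SMM every mutation moves one repeat unit;
under the TPM a mutation is multistep with probability 0.30, with geometric
step lengths parametrized by their variance (default 30, giving geometric
parameter 1/6). The k = n case is returned analytically (every allele a
singleton forces unbiased H = 1 exactly), and k = 1 gives (0, 0).

The per-population test is a one-tailed Wilcoxon signed-rank over loci for
heterozygosity excess. Two conventions matter and are deliberate:

1. **Standardization.** Ranks are taken on (H<sub>E</sub> − centre)/sd, not
   raw differences, so low-k loci with wide conditional distributions do not
   dominate the ranking.
2. **Median centring.** The conditional distribution of H given k is
   left-skewed, so differences from the conditional *mean* have a positive
   median even at equilibrium, and the signed-rank test — whose null assumes
   sign balance — over-rejects several-fold. An oracle experiment replacing
   the simulated H<sub>eq</sub> with the exact ensemble-conditional mean
   still rejected at ~0.15 at the 0.05 level over 20 loci, proving the
   inflation is intrinsic to mean-centring and not an estimation artifact.
   Centring each locus on the conditional *median* restores sign balance;
   equilibrium rejection is then 0.02–0.04. The per-locus report still
   carries the conditional mean, sd and standardized difference.

Equilibrium H<sub>eq</sub> values are cached by (n, k, model, reps, seed),
which makes repeated tests over many loci and datasets cheap. The Wilcoxon
p-value comes from scipy, exact for small locus counts without ties and a
continuity-corrected normal approximation otherwise.

Calibration and power experiments use surveys of 25 diploids × 20 loci with
per-locus mutation rates Gamma(shape 2)-distributed around the mean — rate
heterogeneity is a property of real microsatellite panels and of the GSM
model below, and a shared single rate would artificially decouple each
locus's allele count from its own θ. At an ancestral θ of 5 the equilibrium
rejection rate is ≈ 0.03; a 100-fold crash one (current-size) N generations
before sampling — the transient window in which rare alleles have been lost
but gene diversity persists — is detected in ≈ 60–65% of surveys. Much more
recent or much older crashes leave the excess signature respectively
undeveloped or already decayed.

## Coalescent simulator

Genealogies come from msprime's structured coalescent with time in
generations and diploid population sizes (pairwise coalescence rate
k(k−1)/4N). The four demographic models share the topology: dom splits from
siev at T3, ori from siev at T2, sylv from siev at T1, with 0 < T3 < T2 <
T1; ancestral lineages keep the parent population's size unless overridden.
Admixture pulses are instantaneous lineage movements at fixed times —
600 generations (ori↔dom), 200 (sylv↔dom), 13 (dom→siev) — expressed
backward in time as mass migrations (each recipient lineage moves to the
donor with probability r). Model *a* has all five pulses (r1…r5), *b* keeps
only the two into dom (r2, r5), *c* keeps only sylv→dom (r2), and *d* has
none. Scenario validation enforces the time ordering and that every pulse
precedes the splits of both populations involved (so models a/b require
T3 > 600 and model c requires T3 > 200). A preset moves the sylv pulse to
67 generations for the "recent European admixture" variant.

Mutations are overlaid per locus on the single genealogical tree (no
recombination within a locus; loci independent) as a Poisson process of rate
μ<sub>L</sub> + μ<sub>SNI,L</sub> per lineage-generation, walking the tree
in preorder in a numba kernel. Each event is a GSM step with probability
μ<sub>L</sub>/(μ<sub>L</sub>+μ<sub>SNI,L</sub>): the length changes by
±motif_len × G nucleotides with G ~ Geometric(P<sub>L</sub>) (support ≥ 1)
and a fair sign, constrained to the locus's window of contiguous lattice
states (40 states; 44 and 42 for the two wide loci of the inference panel)
by resampling steps that would exit — resampling rather than reflection
keeps the realized step-length distribution conditional-geometric and avoids
probability pile-up at the window edges. Otherwise the event is a
single-nucleotide indel of ±1 nt, unconstrained, which takes the allele off
the motif lattice. The root allele is the lattice midpoint; every statistic
downstream is translation invariant, so this choice is inert (asserted by
test). Simulated gene copies are paired into diploids uniformly at random
within each population.

Mutation hyperparameters follow the generalized stepwise model's hierarchy:
a dataset-level mean rate μ ~ U(10⁻⁴, 10⁻³) per generation, mean geometric
parameter P ~ U(0.1, 0.3), and mean indel rate μ<sub>SNI</sub> log-uniform
on (10⁻⁸, 10⁻⁴); per-locus values are Gamma(shape 2, mean as drawn),
resampled into the truncation windows μ<sub>L</sub> ∈ [5×10⁻⁵, 5×10⁻²] and
P<sub>L</sub> ∈ [0.01, 0.9].

## Approximate Bayesian computation

**Summary statistics** (the inference panel's 14 perfect-repeat loci): per
population the mean number of alleles per locus and mean unbiased gene
diversity; per population pair the multilocus Weir–Cockerham θ and the
Goldstein (δμ)² distance (squared difference of mean repeat counts, averaged
over loci) — 2P + 2·C(P,2) = 20 statistics for the four populations.

**Priors.** Demographic priors are uniform: N<sub>1..4</sub> on (10, 10⁵)
diploids, T1 on (2,000, 10⁵), T2 on (600, 2×10⁴), T3 on (200, 10⁴)
generations, admixture proportions on (0, 1), with draws rejected until the
ordering and pulse-before-split constraints hold. These bounds are package
configuration — broad enough to contain the plausible *Malus* histories.

**Distance and retention.** Statistics are centred and scaled by the pooled
median and MAD (degenerate columns dropped); the Euclidean distance to the
observed vector selects the closest `tolerance_frac` of rows, with ties
broken by a seeded permutation so that duplicate rows from different tables
are retained without positional bias.

**Model choice.** Model identity is regressed on (stats − observed) for the
retained rows by multinomial logistic regression; the posterior probability
of each model is the fitted category probability at the origin, with 95%
confidence intervals from the delta method on the ML covariance (only the
intercept block contributes at the origin), truncated to [0, 1]. Columns are
standardized before fitting (the probabilities at the origin are invariant
to column scaling); a newton → bfgs fallback chain handles ill-conditioned
fits, and if both fail the retained category frequencies with binomial
intervals are reported instead, with a warning. Retention is pooled across
models, so a model's prior predictive density near the data shows up as its
share of retained rows; the default tolerance of 1% mirrors standard
practice.

**Parameter estimation.** Retained draws get Epanechnikov weights on
distance scaled to the retention radius. Each parameter is mapped by a logit
to its prior bounds (on the log scale for the log-uniform indel rate), so
adjusted draws can never leave the prior support; a weighted linear
regression of the transformed parameters on (stats − observed) gives
adjusted draws = fitted-at-observed + residuals. A singular design falls
back to the unadjusted rejection posterior with a warning. Modes are taken
from a weighted Gaussian KDE (Silverman bandwidth) on the back-transformed
scale; intervals are weighted 2.5/97.5% quantiles. The composites
θ<sub>i</sub> = 4N<sub>i</sub>μ and τ<sub>j</sub> = μT<sub>j</sub> are
computed per adjusted draw, never from marginal summaries. The parameter
tolerance should keep retained rows well above the number of statistics:
with 5,000 simulations per model we use 10% (500 rows against 21
predictors); at the full 5×10⁵-simulation scale such analyses usually run, the classical 1% gives 5,000 rows.

**Model checking.** Pseudo-observed datasets are simulated from parameter
vectors drawn (with weights) from the adjusted posterior — draws violating
the scenario constraints after adjustment are redrawn — and each observed
statistic is located in its posterior-predictive distribution (fraction of
simulated values below it).

**Time conversion.** Generations convert to years with a generation time of
7.5 years (a 5–10-year juvenile phase), e.g. the domestication-split mode of
2,360 generations → 17,700 years.

## Recovery experiments and their scales

The scaled-down validation design uses 25 diploids per population, 14 loci,
and 5,000 simulations per model — sizes chosen so the full four-model
experiment runs in minutes on one CPU while the retained sets remain large
enough for the regressions. Pseudo-observed data are generated under model
*c* with r2 = 0.6 and a truth vector (N1 = 3,000, N2 = 8,000, N3 = 12,000,
N4 = 15,000, T1 = 30,000, T2 = 5,000, T3 = 2,000, μ = 3×10⁻⁴) in which every
wild population has appreciable drift: a recovery experiment needs each
admixture edge that distinguishes the models to be statistically visible,
and histories with very large wild N make the extra pulses of models *a*/*b*
nearly inert, collapsing the model comparison to a coin flip regardless of
method. At this design, model *c* ranks first in ~9/10 replicates and the
95% credibility interval for r2 covers 0.6 in ~10/10; the remaining
confusion is with model *b*, which nests *c* (its extra ori→dom pulse can be
near zero) and is penalized only through the prior mass it spends away from
r5 ≈ 0. Across independent reference-table realizations the model-choice
win rate varies noticeably — 5,000 simulations per model is the edge of
what the 20-statistic local regression can support.

## Synthetic survey generator

The generator emulates a five-species microsatellite survey: sample sizes
299/215/168/40/48 diploids, 26 loci, allele frequencies drawn by cascaded
Balding–Nichols draws along a UPGMA tree of the target F<sub>ST</sub> matrix
(pattern: dom–sylv ≈ 0.006 up to bacc–sylv ≈ 0.17). A flat star topology
cannot reproduce that pattern — dom and sylv must share most of their drift
history — which is why the drift is tree-structured. Per-edge drift
parameters are initialised from the UPGMA branch lengths (pairwise
F<sub>ST</sub> is approximately additive along paths for small drift) and
rescaled multiplicatively against the realized Weir–Cockerham estimates of
freshly generated genotypes until every pair is within the configured
relative tolerance (default 25%, against a ±30% contract). Base diversity
(12 alleles per locus, Dirichlet(2) ancestral frequencies) puts per-species
H<sub>E</sub> near the 0.75–0.87 range of real surveys.

On top of the base survey the generator plants, and records in a truth
object: admixed individuals (one gamete from the home pool, one from a wild
donor — true membership 0.5/0.5), misclassified individuals (wild labels
with fully domesticated genotypes), full-sib pairs (two offspring of one
simulated parent pair), near-clone pairs (each planted difference mutates
one locus so the sorted-pair mismatch distance increases by exactly one),
null alleles (heterozygous carriers become apparent homozygotes, double
carriers become missing) and missing data. Planted pairs are exempt from the
null/missing perturbations so the truth record stays exact. The truth
record suffices to score clonal assignment and admixture screening with zero
confusion at matched thresholds.

What these experiments do **not** show: the generator draws genotypes in
Hardy–Weinberg proportions within species, has no geographic substructure,
clines, linkage, genotyping error beyond the planted null alleles, or
pedigree structure beyond the planted pairs; passing on it demonstrates the
estimators and screening rules, not robustness to those real-data features.

## Known limitations

- The bottleneck H<sub>eq</sub> estimator conditions on a point θ tuned to
  k; the residual mean bias by k is visible in the per-locus standardized
  differences even though the median-centred test is calibrated.
- Model-choice confidence intervals are asymptotic (ML covariance); at a few
  hundred retained rows they can be optimistic.
- The simulator validates and exposes only the four preset topologies; the
  event engine itself is general but untested beyond them.
- GENEPOP population labels rely on the `POP <label>` extension; files from
  other writers fall back to positional labels `pop_1`, `pop_2`, …
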