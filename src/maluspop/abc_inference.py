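"""Approximate Bayesian computation for the divergence-with-admixture models.

Implements the classic rejection + regression ABC workflow on microsatellite
summary statistics: reference tables of prior draws paired with simulated
statistics; model choice by polychotomous (multinomial) logistic regression on
the closest fraction of simulations, with confidence intervals from the
asymptotic covariance of the maximum-likelihood estimates; parameter
estimation by local linear regression with Epanechnikov weights after a logit
transform of parameters to their prior bounds; posterior-predictive model
checking against pseudo-observed datasets; and generation-to-year conversion.

Summary statistics per dataset: for every population the mean number of
alleles per locus and the mean (unbiased) gene diversity; for every population
pair the multilocus Weir-Cockerham F_ST and the Goldstein (delta mu)^2
distance (squared difference of mean repeat counts, averaged over loci).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gaussian_kde

from .coalescent_sim import (DemographicScenario, DatasetMutationParams,
                             MutationHyperparams, build_scenario,
                             default_abc_loci, draw_locus_params,
                             simulate_genotype_arrays)
from .genotype_io import MISSING, GenotypeTable, LocusDef, PopulationMap
from .popgen_stats import _multilocus_theta, nei_unbiased_diversity

__all__ = [
    "ObservedStats", "ReferenceTable", "ModelPosterior", "ParamPosterior",
    "AnalysisConfig", "DemographicPriors", "summary_stats",
    "stats_from_arrays", "build_reference_table", "model_posterior",
    "param_posterior", "posterior_predictive_check", "generations_to_years",
]


@dataclass
class AnalysisConfig:
    """Tolerance, generation time and bookkeeping for an ABC analysis."""

    generation_time: float = 7.5   # years per generation (juvenile phase 5-10 y)
    tolerance_frac: float = 0.01
    n_sims: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")
        if not 0 < self.tolerance_frac <= 1:
            raise ValueError("tolerance_frac must be in (0, 1]")


def generations_to_years(value: float, config: AnalysisConfig) -> float:
    """Convert a time in generations to years using the configured generation time."""
    return value * config.generation_time


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass
class ObservedStats:
    """Ordered summary-statistic vector with labels."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.labels):
            raise ValueError("values/labels length mismatch")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.labels)


def stat_labels(pop_names: list[str]) -> list[str]:
    labels = [f"A_{p}" for p in pop_names] + [f"H_{p}" for p in pop_names]
    for a, b in combinations(pop_names, 2):
        labels.append(f"FST_{a}_{b}")
    for a, b in combinations(pop_names, 2):
        labels.append(f"dmu2_{a}_{b}")
    return labels


def _wc_pair_ad(n1, p1, h1, n2, p2, h2):
    """Summed WC (a, a+b+c) components for two populations at one locus.

    Inputs are individual counts plus per-allele frequency and
    heterozygote-carrier proportion vectors on a shared allele support.
    """
    r = 2.0
    n = np.array([n1, n2], dtype=float)
    nsum = n1 + n2
    nbar = nsum / r
    if nbar <= 1:
        return 0.0, 0.0
    nc = (nsum - (n1 * n1 + n2 * n2) / nsum) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / nsum
    hbar = (n1 * h1 + n2 * h2) / nsum
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float((a + b + c).sum())


def stats_from_arrays(arrays, loci: list[LocusDef],
                      pop_names: list[str]) -> ObservedStats:
    """Summary statistics from per-locus, per-population genotype arrays.

    ``arrays[j][pop]`` is an (n, 2) allele-length array at locus ``j`` (missing
    rows already removed).  Loci with no scored copies in a population are
    skipped for the statistics involving it.  Per-population allele summaries
    are computed once per locus and shared by all pairwise statistics.
    """
    P = len(pop_names)
    n_loci = len(arrays)
    pairs = list(combinations(range(P), 2))
    k_acc = [[] for _ in range(P)]
    h_acc = [[] for _ in range(P)]
    a_acc = [[0.0, 0.0] for _ in pairs]        # summed a and a+b+c
    d_acc = [[] for _ in pairs]

    for j in range(n_loci):
        pooled = [arrays[j][pop] for pop in pop_names]
        present = [g.size > 0 for g in pooled]
        union = np.unique(np.concatenate(
            [g.ravel() for g, ok in zip(pooled, present) if ok]))
        freqs, hets, ns, means = [None] * P, [None] * P, [0] * P, [np.nan] * P
        for pi in range(P):
            if not present[pi]:
                continue
            g = pooled[pi]
            ai = np.searchsorted(union, g)
            counts = np.bincount(ai.ravel(), minlength=union.size)
            n_ind = len(g)
            p = counts / (2 * n_ind)
            het = g[:, 0] != g[:, 1]
            hc = np.zeros(union.size)
            if het.any():
                hg = ai[het]
                hc = (np.bincount(hg[:, 0], minlength=union.size)
                      + np.bincount(hg[:, 1], minlength=union.size))
            freqs[pi], hets[pi], ns[pi] = p, hc / n_ind, n_ind
            k_acc[pi].append(int((counts > 0).sum()))
            ssq = float(p @ p)
            n_genes = 2 * n_ind
            h_acc[pi].append(n_genes * (1.0 - ssq) / (n_genes - 1)
                             if n_genes > 1 else np.nan)
            means[pi] = float(loci[j].repeat_count(union) @ p)
        for pk, (x, y) in enumerate(pairs):
            if not (present[x] and present[y]):
                continue
            if union.size >= 2:
                a, d = _wc_pair_ad(ns[x], freqs[x], hets[x],
                                   ns[y], freqs[y], hets[y])
                a_acc[pk][0] += a
                a_acc[pk][1] += d
            d_acc[pk].append((means[x] - means[y]) ** 2)

    a_mean = np.array([np.mean(k) if k else np.nan for k in k_acc])
    h_mean = np.array([np.nanmean(h) if h else np.nan for h in h_acc])
    fst = np.array([acc[0] / acc[1] if acc[1] != 0 else np.nan
                    for acc in a_acc])
    dmu2 = np.array([np.mean(d) if d else np.nan for d in d_acc])
    values = np.concatenate([a_mean, h_mean, fst, dmu2])
    return ObservedStats(values=values, labels=stat_labels(pop_names))


def summary_stats(table: GenotypeTable, pops: PopulationMap,
                  pop_order: list[str] | None = None) -> ObservedStats:
    """Summary statistics of a genotype table (missing calls dropped per locus)."""
    pop_order = pop_order or pops.labels()
    if len(pop_order) < 2:
        raise ValueError("need at least two populations")
    rows_of = {p: [] for p in pop_order}
    for i, ind in enumerate(table.individuals):
        p = pops[ind]
        if p in rows_of:
            rows_of[p].append(i)
    arrays = []
    for j in range(table.n_loci):
        d = {}
        for p in pop_order:
            g = table.calls[rows_of[p], j, :]
            d[p] = g[g[:, 0] != MISSING]
        arrays.append(d)
    return stats_from_arrays(arrays, table.loci, pop_order)


# ---------------------------------------------------------------------------
# Priors and reference tables
# ---------------------------------------------------------------------------

_MODEL_R_PARAMS = {"a": ["r1", "r2", "r3", "r4", "r5"],
                   "b": ["r2", "r5"], "c": ["r2"], "d": []}


@dataclass
class DemographicPriors:
    """Uniform prior bounds for the demographic parameters.

    Divergence-time draws are rejected until the ordering T3 < T2 < T1 and the
    model's admixture-before-split constraints hold.  Mutation hyperpriors
    follow :class:`MutationHyperparams`.
    """

    n_bounds: tuple[float, float] = (10.0, 1e5)
    t1_bounds: tuple[float, float] = (2_000.0, 100_000.0)
    t2_bounds: tuple[float, float] = (600.0, 20_000.0)
    t3_bounds: tuple[float, float] = (200.0, 10_000.0)
    r_bounds: tuple[float, float] = (0.0, 1.0)
    mutation: MutationHyperparams = field(default_factory=MutationHyperparams)
    admix_times: dict[str, float] | None = None

    def param_names(self, model_id: str) -> list[str]:
        return (["N1", "N2", "N3", "N4", "T1", "T2", "T3"]
                + _MODEL_R_PARAMS[model_id]
                + ["mu_mean", "p_mean", "mu_sni_mean"])

    def bounds_table(self, model_id: str):
        """Per-parameter (lo, hi, log-scale flag) for the logit transform."""
        m = self.mutation
        out = {"N1": (*self.n_bounds, False), "N2": (*self.n_bounds, False),
               "N3": (*self.n_bounds, False), "N4": (*self.n_bounds, False),
               "T1": (*self.t1_bounds, False), "T2": (*self.t2_bounds, False),
               "T3": (*self.t3_bounds, False)}
        for r in _MODEL_R_PARAMS[model_id]:
            out[r] = (*self.r_bounds, False)
        out["mu_mean"] = (*m.mu_mean_bounds, False)
        out["p_mean"] = (*m.p_mean_bounds, False)
        out["mu_sni_mean"] = (*m.mu_sni_bounds, True)
        return out

    def draw_scenario(self, model_id: str, rng, max_rejections: int = 10_000):
        """One accepted prior draw: (scenario, params dict). Rejection-sampled."""
        for _ in range(max_rejections):
            p = {f"N{i}": rng.uniform(*self.n_bounds) for i in range(1, 5)}
            p["T1"] = rng.uniform(*self.t1_bounds)
            p["T2"] = rng.uniform(*self.t2_bounds)
            p["T3"] = rng.uniform(*self.t3_bounds)
            for r in _MODEL_R_PARAMS[model_id]:
                p[r] = rng.uniform(*self.r_bounds)
            try:
                scen = build_scenario(model_id, **{k: v for k, v in p.items()},
                                      admix_times=self.admix_times)
            except ValueError:
                continue
            return scen, p
        raise RuntimeError(
            f"prior inconsistent with model {model_id!r} constraints: "
            f"no accepted draw in {max_rejections} attempts")


@dataclass
class ReferenceTable:
    """Prior draws paired with simulated summary-statistic vectors."""

    model_id: str
    params: pd.DataFrame
    stats: np.ndarray
    stat_labels: list[str]
    prior_bounds: dict[str, tuple[float, float, bool]]
    n_sims: int

    def to_frame(self) -> pd.DataFrame:
        s = pd.DataFrame(self.stats, columns=self.stat_labels,
                         index=self.params.index)
        return pd.concat([self.params, s], axis=1)


def build_reference_table(model_id: str, priors: DemographicPriors,
                          samples: dict[str, int], n_sims: int,
                          seed: int = 1, n_loci: int = 14) -> ReferenceTable:
    """Simulate ``n_sims`` (prior draw -> dataset -> statistics) rows."""
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    loci = default_abc_loci(n_loci)
    pop_names = list(samples)
    names = priors.param_names(model_id)
    param_rows = np.empty((n_sims, len(names)))
    stat_rows = None
    for s in range(n_sims):
        scen, p = priors.draw_scenario(model_id, rng)
        mut = draw_locus_params(priors.mutation, loci, rng)
        arrays, _ = simulate_genotype_arrays(
            scen, mut, samples, n_loci=n_loci,
            seed=int(rng.integers(1, 2**31 - 1)))
        st = stats_from_arrays(arrays, loci, pop_names)
        if stat_rows is None:
            stat_rows = np.empty((n_sims, st.values.size))
            labels = st.labels
        stat_rows[s] = st.values
        p.update(mu_mean=mut.mu_mean, p_mean=mut.p_mean,
                 mu_sni_mean=mut.mu_sni_mean)
        param_rows[s] = [p[k] for k in names]
    params = pd.DataFrame(param_rows, columns=names)
    return ReferenceTable(model_id=model_id, params=params, stats=stat_rows,
                          stat_labels=labels,
                          prior_bounds=priors.bounds_table(model_id),
                          n_sims=n_sims)


# ---------------------------------------------------------------------------
# Distance normalization and retention
# ---------------------------------------------------------------------------

def _median_mad_scale(stats: np.ndarray, obs: np.ndarray):
    """Centre/scale columns by pooled median and MAD; drop degenerate columns."""
    med = np.nanmedian(stats, axis=0)
    mad = np.nanmedian(np.abs(stats - med), axis=0)
    keep = mad > 0
    mad_safe = np.where(keep, mad, 1.0)
    zs = (stats - med) / mad_safe
    zo = (obs - med) / mad_safe
    zs[:, ~keep] = 0.0
    zo[~keep] = 0.0
    zs = np.nan_to_num(zs, nan=0.0)
    zo = np.nan_to_num(zo, nan=0.0)
    return zs, zo


def _retain(stats: np.ndarray, obs: np.ndarray, tolerance_frac: float,
            seed: int = 0):
    zs, zo = _median_mad_scale(stats, obs)
    d = np.sqrt(((zs - zo) ** 2).sum(axis=1))
    m = max(2, int(np.ceil(tolerance_frac * len(d))))
    # ties broken by a seeded permutation so that equal-distance rows from
    # different reference tables are retained without positional bias
    tie = np.random.default_rng(seed).permutation(len(d))
    idx = np.lexsort((tie, d))[:m]
    return idx, d[idx], zs[idx] - zo


# ---------------------------------------------------------------------------
# Model choice
# ---------------------------------------------------------------------------

@dataclass
class ModelPosterior:
    """Posterior model probabilities with 95% confidence bounds."""

    table: pd.DataFrame   # index: model id; columns: p, ci2.5, ci97.5
    method: str


def model_posterior(refs: list[ReferenceTable], obs: ObservedStats,
                    config: AnalysisConfig) -> ModelPosterior:
    """Model probabilities by polychotomous logistic regression.

    The reference tables are pooled; statistics are centred and scaled by the
    pooled median/MAD; the ``tolerance_frac`` closest simulations to the
    observed vector are retained, and model identity is regressed on the
    (stats - observed) differences.  The posterior probability of each model
    is the fitted category probability at the zero vector, with confidence
    intervals from the asymptotic (delta-method) covariance of the ML
    coefficients, truncated to [0, 1].
    """
    labels0 = refs[0].stat_labels
    for r in refs:
        if r.stat_labels != labels0:
            raise ValueError("reference tables have differing statistics")
    model_ids = [r.model_id for r in refs]
    pooled = np.vstack([r.stats for r in refs])
    owner = np.concatenate([np.full(r.stats.shape[0], i)
                            for i, r in enumerate(refs)])
    if len(pooled) < 1 / config.tolerance_frac:
        raise ValueError("pooled reference rows < 1/tolerance_frac")
    idx, _, x = _retain(pooled, obs.values, config.tolerance_frac, config.seed)
    y = owner[idx]

    present = np.unique(y)
    absent = [m for i, m in enumerate(model_ids) if i not in present]
    if absent:
        warnings.warn(f"models absent from retained set: {absent}; "
                      "their probability is reported as 0")

    probs, ci_lo, ci_hi, method = _fit_multinomial(x, y, present, len(model_ids))
    tab = pd.DataFrame({"p": probs, "ci2.5": ci_lo, "ci97.5": ci_hi},
                       index=model_ids)
    return ModelPosterior(table=tab, method=method)


def _fit_multinomial(x, y, present, n_models):
    """Fit MNLogit on retained rows; fall back to rejection frequencies."""
    import statsmodels.api as sm

    probs = np.zeros(n_models)
    ci_lo = np.zeros(n_models)
    ci_hi = np.zeros(n_models)
    # recode categories to 0..m-1 over present models
    recode = {m: i for i, m in enumerate(present)}
    yy = np.array([recode[v] for v in y])
    m = len(present)
    if m == 1:
        probs[present[0]] = 1.0
        ci_lo[present[0]] = ci_hi[present[0]] = 1.0
        return probs, ci_lo, ci_hi, "single-model"
    # drop constant columns and standardize the rest: the fitted category
    # probabilities at x = 0 are invariant to column scaling, which only
    # improves the conditioning of the optimisation
    keep = x.std(axis=0) > 1e-12
    xs = x[:, keep] / x[:, keep].std(axis=0)
    X = sm.add_constant(xs, has_constant="add")
    try:
        fit = None
        last_err = None
        for method in ("newton", "bfgs"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cand = sm.MNLogit(yy, X).fit(method=method, maxiter=1000,
                                                 disp=0)
                beta_c = np.asarray(cand.params)
                cov_c = np.asarray(cand.cov_params())
                if np.all(np.isfinite(beta_c)) and np.all(np.isfinite(cov_c)):
                    fit = cand
                    break
            except Exception as err:  # singular Hessian, separation, ...
                last_err = err
        if fit is None:
            raise last_err or np.linalg.LinAlgError("MNLogit did not converge")
        beta = np.asarray(fit.params)          # (k_vars, m-1)
        cov = np.asarray(fit.cov_params())     # flattened, column-major
        b0 = beta[0]                            # intercepts
        e = np.exp(np.concatenate([[0.0], b0]))
        p = e / e.sum()
        k_vars = beta.shape[0]
        for j in range(m):
            # gradient of p_j wrt flattened params (only intercept rows nonzero)
            g = np.zeros((k_vars, m - 1))
            for c in range(1, m):
                g[0, c - 1] = p[j] * ((1.0 if j == c else 0.0) - p[c])
            gf = g.ravel(order="F")
            var = float(gf @ cov @ gf)
            sd = np.sqrt(max(var, 0.0))
            probs[present[j]] = p[j]
            ci_lo[present[j]] = min(max(p[j] - 1.96 * sd, 0.0), 1.0)
            ci_hi[present[j]] = min(max(p[j] + 1.96 * sd, 0.0), 1.0)
        return probs, ci_lo, ci_hi, "mnlogit"
    except Exception:
        # rejection frequencies with binomial normal CI
        n = len(yy)
        for j in range(m):
            pj = float((yy == j).mean())
            sd = np.sqrt(pj * (1 - pj) / n)
            probs[present[j]] = pj
            ci_lo[present[j]] = max(pj - 1.96 * sd, 0.0)
            ci_hi[present[j]] = min(pj + 1.96 * sd, 1.0)
        warnings.warn("multinomial regression failed; reporting rejection "
                      "frequencies")
        return probs, ci_lo, ci_hi, "rejection"


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

def _logit_fwd(x, lo, hi, log_scale):
    if log_scale:
        x, lo, hi = np.log(x), np.log(lo), np.log(hi)
    span = hi - lo
    if span <= 0:
        return np.zeros_like(np.asarray(x, dtype=float)), True
    u = np.clip((x - lo) / span, 1e-9, 1 - 1e-9)
    return np.log(u / (1 - u)), False


def _logit_back(y, lo, hi, log_scale):
    if log_scale:
        lo, hi = np.log(lo), np.log(hi)
    x = lo + (hi - lo) * expit(y)
    return np.exp(x) if log_scale else x


@dataclass
class ParamPosterior:
    """Posterior summaries plus the adjusted accepted draws."""

    summary: pd.DataFrame        # index: parameter; columns: mode, ci2.5, ci97.5
    draws: pd.DataFrame          # adjusted accepted draws (one row per sim)
    weights: np.ndarray
    adjusted: bool


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(q, cw, x)


def _mode_kde(x, w):
    if np.allclose(x, x[0]):
        return float(x[0])
    try:
        kde = gaussian_kde(x, bw_method="silverman", weights=w)
    except np.linalg.LinAlgError:
        return float(_weighted_quantile(x, w, 0.5))
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def param_posterior(ref: ReferenceTable, obs: ObservedStats,
                    config: AnalysisConfig, adjust: bool = True,
                    kernel: str = "epanechnikov") -> ParamPosterior:
    """Posterior parameter distributions by local linear regression.

    The closest ``tolerance_frac`` simulations are retained with Epanechnikov
    weights on the (median/MAD-normalized) distance scaled to the retention
    radius.  Parameters are logit-mapped to their prior bounds (log scale
    where the prior is log-uniform), regressed on the (stats - observed)
    differences by weighted least squares, and the draws adjusted to the
    fitted value at the observed statistics plus residuals.  Modes are
    estimated by weighted Gaussian KDE (Silverman bandwidth) on the
    back-transformed scale; intervals are weighted 2.5/97.5% quantiles.
    Composite parameters theta_i = 4 N_i mu and tau_j = mu T_j are computed
    per adjusted draw.

    ``adjust=False`` (or a singular regression design) gives the plain
    rejection posterior; ``kernel="uniform"`` disables distance weighting.
    """
    idx, d, x = _retain(ref.stats, obs.values, config.tolerance_frac, config.seed)
    if kernel == "epanechnikov":
        dmax = d.max()
        w = 1.0 - (d / dmax) ** 2 if dmax > 0 else np.ones_like(d)
        w = np.maximum(w, 1e-12)
    elif kernel == "uniform":
        w = np.ones_like(d)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    names = list(ref.params.columns)
    raw = ref.params.to_numpy()[idx]
    adjusted_cols = {}
    did_adjust = False
    # regression design shared by all parameters
    keep = x.std(axis=0) > 1e-12
    X = np.column_stack([np.ones(len(x)), x[:, keep]])
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    use_reg = adjust and np.linalg.matrix_rank(Xw) == X.shape[1]
    if adjust and not use_reg:
        warnings.warn("singular regression design; falling back to the "
                      "unadjusted rejection posterior")
    for pi, name in enumerate(names):
        lo, hi, log_scale = ref.prior_bounds[name]
        y, degenerate = _logit_fwd(raw[:, pi], lo, hi, log_scale)
        if degenerate:
            adjusted_cols[name] = raw[:, pi]
            continue
        if use_reg:
            beta, *_ = np.linalg.lstsq(Xw, y * sw, rcond=None)
            fitted0 = beta[0]                       # fitted value at x = 0
            resid = y - X @ beta
            y_adj = fitted0 + resid
            did_adjust = True
        else:
            y_adj = y
        adjusted_cols[name] = _logit_back(y_adj, lo, hi, log_scale)

    draws = pd.DataFrame(adjusted_cols)
    mu = draws["mu_mean"].to_numpy() if "mu_mean" in draws else None
    if mu is not None:
        for i in range(1, 5):
            if f"N{i}" in draws:
                draws[f"theta{i}"] = 4.0 * draws[f"N{i}"].to_numpy() * mu
        for j in range(1, 4):
            if f"T{j}" in draws:
                draws[f"tau{j}"] = mu * draws[f"T{j}"].to_numpy()

    rows = []
    for name in draws.columns:
        v = draws[name].to_numpy()
        mode = _mode_kde(v, w)
        q = _weighted_quantile(v, w, [0.025, 0.975])
        rows.append((name, mode, q[0], q[1]))
    summary = pd.DataFrame(rows, columns=["parameter", "mode", "ci2.5",
                                          "ci97.5"]).set_index("parameter")
    return ParamPosterior(summary=summary, draws=draws, weights=w,
                          adjusted=did_adjust)


# ---------------------------------------------------------------------------
# Posterior-predictive model checking
# ---------------------------------------------------------------------------

def posterior_predictive_check(model_id: str, posterior: ParamPosterior,
                               samples: dict[str, int], obs: ObservedStats,
                               n_pods: int = 100, seed: int = 0,
                               n_loci: int = 14,
                               admix_times: dict[str, float] | None = None
                               ) -> pd.Series:
    """Tail probabilities of each observed statistic under the posterior.

    ``n_pods`` parameter vectors are drawn (with weights) from the adjusted
    posterior draws; a dataset is simulated from each and its statistics
    computed.  Reports, per statistic, the fraction of simulated values lying
    below the observed value.
    """
    if n_pods < 1:
        raise ValueError("n_pods must be >= 1")
    if len(posterior.draws) < 50:
        raise ValueError("need at least 50 posterior draws")
    rng = np.random.default_rng(seed)
    loci = default_abc_loci(n_loci)
    pop_names = [p for p in ("dom", "ori", "siev", "sylv") if p in samples] \
        or list(samples)
    w = posterior.weights / posterior.weights.sum()
    sims = np.empty((n_pods, obs.values.size))
    made = 0
    attempts = 0
    while made < n_pods:
        attempts += 1
        if attempts > 100 * n_pods:
            raise RuntimeError("could not draw valid posterior parameter "
                               "vectors for pseudo-observed datasets")
        row = posterior.draws.iloc[int(rng.choice(len(w), p=w))]
        try:
            scen = build_scenario(
                model_id,
                **{k: float(row[k]) for k in
                   ("N1", "N2", "N3", "N4", "T1", "T2", "T3")},
                **{r: float(row[r]) for r in _MODEL_R_PARAMS[model_id]},
                admix_times=admix_times)
        except ValueError:
            continue
        hyper = MutationHyperparams(
            mu_mean_bounds=(row["mu_mean"], row["mu_mean"]),
            p_mean_bounds=(row["p_mean"], row["p_mean"]),
            mu_sni_bounds=(row["mu_sni_mean"], row["mu_sni_mean"]))
        mut = draw_locus_params(hyper, loci, rng)
        arrays, _ = simulate_genotype_arrays(
            scen, mut, samples, n_loci=n_loci,
            seed=int(rng.integers(1, 2**31 - 1)))
        sims[made] = stats_from_arrays(arrays, loci, pop_names).values
        made += 1
    below = np.nanmean(sims < obs.values[None, :], axis=0)
    return pd.Series(below, index=obs.labels, name="tail_prob")
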