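"""Effective sex ratio from autosomal versus sex-linked drift.

Drift since divergence is summarised per marker class as a branch length on
the diffusion time scale, tau = t / (2 Ne).  Because the sex chromosome
spends unequal time in the two sexes, the ratio tau(sex) / tau(auto) encodes
the effective sex ratio; with tau(A) = t/(2 Ne_A) and tau(X) = t/(2 Ne_X)
the proportion of females in the effective population is

    epsilon = 2 - (9/8) * tau(X) / tau(A)

which equals N_f / (N_f + N_m) exactly under the standard sex-specific
effective-size expressions for an X (homogametic females) system.  Applied
to Z data (birds: homogametic males) the identical arithmetic instead
recovers the proportion of males; the ``heterogamety`` flag only relabels
the interpretation, the formula is always evaluated as printed.

Two tau estimators are provided: a moment estimator contrasting sample
frequencies with ancestral/reference frequencies, and a hierarchical
Bayesian random-walk Metropolis sampler with a truncated-normal (Nicholson)
approximation to the time-dependent drift diffusion, valid in the small-tau
regime.  Pseudo-replication resamples SNP panels (default 50 replicates of
5,000 autosomal + 5,000 sex-linked SNPs) and reports the per-replicate
epsilon distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class TauEstimate:
    population: str
    marker_class: str          # "autosomal" or "sex_linked"
    tau: float
    se: float
    method: str                # "moments" or "mcmc"
    n_snps: int = 0

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be non-negative")


@dataclass
class ESREstimate:
    population: str
    epsilon: float                   # mean over replicates
    replicate_values: np.ndarray
    n_replicates: int
    replicate_tau_auto: np.ndarray = field(default_factory=lambda: np.empty(0))
    replicate_tau_sex: np.ndarray = field(default_factory=lambda: np.empty(0))
    heterogamety: str = "XY"

    @property
    def interpretation(self) -> str:
        """What the printed formula's output measures under each system."""
        return ("proportion of females" if self.heterogamety == "XY"
                else "proportion of males")


@dataclass
class MCMCSchedule:
    pilot_runs: int = 20
    pilot_iters: int = 500
    iters: int = 20_000
    thin: int = 20
    burn_in: int = 10_000

    def __post_init__(self):
        if self.burn_in >= self.iters:
            raise ValueError("burn_in must be smaller than iters")
        if min(self.pilot_runs, self.pilot_iters, self.thin) < 1:
            raise ValueError("schedule counts must be positive")


@dataclass
class ESRConfig:
    n_replicates: int = 50
    n_autosomal_snps: int = 5000
    n_sex_snps: int = 5000
    mcmc: MCMCSchedule = field(default_factory=MCMCSchedule)
    seed: int | None = None
    heterogamety: str = "auto"       # auto | XY | ZW
    method: str = "moments"          # moments | mcmc

    def __post_init__(self):
        if min(self.n_replicates, self.n_autosomal_snps, self.n_sex_snps) < 1:
            raise ValueError("counts must be positive")
        if self.heterogamety not in ("auto", "XY", "ZW"):
            raise ValueError("heterogamety must be auto, XY or ZW")
        if self.method not in ("moments", "mcmc"):
            raise ValueError("method must be moments or mcmc")


# ---------------------------------------------------------------------------
# conversion formula
# ---------------------------------------------------------------------------

def esr_from_tau(tau_sex: float, tau_auto: float) -> float:
    """epsilon = 2 - (9/8) tau_sex / tau_auto, reported even outside [0, 1]."""
    if tau_auto <= 0:
        raise ValueError("tau_auto must be positive")
    eps = 2.0 - (9.0 / 8.0) * tau_sex / tau_auto
    if not 0 <= eps <= 1:
        warnings.warn(f"epsilon = {eps:.3f} outside [0, 1] (estimator noise); "
                      "reported unclamped")
    return eps


# ---------------------------------------------------------------------------
# allele frequencies with hemizygosity
# ---------------------------------------------------------------------------

def _infer_heterogamety(matrix: GenotypeMatrix) -> str:
    labels = {c.lower().removeprefix("chr") for c in matrix.chroms[matrix.sex_linked_mask]}
    if "z" in labels or "w" in labels:
        return "ZW"
    return "XY"


def _infer_sexes(matrix: GenotypeMatrix, sex_idx: np.ndarray,
                 heterogamety: str) -> np.ndarray:
    """Sex per sample; unknown sexes classified from sex-chromosome heterozygosity.

    Array platforms call the heterogametic (hemizygous) sex homozygous at
    every sex-linked SNP, so a near-zero heterozygosity rate flags it.
    """
    sexes = matrix.sexes.copy()
    unknown = sexes == "unknown"
    if not unknown.any():
        return sexes
    calls = matrix.calls[:, sex_idx]
    ok = calls != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(ok.sum(axis=1) > 0,
                       ((calls == 1) & ok).sum(axis=1) / np.maximum(ok.sum(axis=1), 1),
                       np.nan)
    cut = max(0.5 * np.nanmean(het), 1e-9)
    hetero_sex = "female" if heterogamety == "ZW" else "male"
    homo_sex = "male" if heterogamety == "ZW" else "female"
    warnings.warn(f"{int(unknown.sum())} sample(s) lack recorded sex; classified "
                  "from sex-chromosome heterozygosity")
    sexes[unknown & (het < cut)] = hetero_sex
    sexes[unknown & (het >= cut)] = homo_sex
    return sexes


def class_frequencies(matrix: GenotypeMatrix, population: str,
                      variant_idx: np.ndarray, sex_linked: bool,
                      heterogamety: str) -> tuple[np.ndarray, float]:
    """(alt frequencies, mean chromosome count) for a population and SNP set.

    For sex-linked SNPs the heterogametic sex contributes one chromosome:
    its array calls are hemizygous-as-homozygous, so its dosage is halved
    and it adds 1 to the chromosome count; the homogametic sex adds 2.
    """
    idx = matrix.pop_indices(population)
    calls = matrix.calls[np.ix_(idx, variant_idx)].astype(float)
    ok = calls != MISSING
    if not sex_linked:
        weights = np.full(idx.size, 2.0)
    else:
        sexes = _infer_sexes(matrix, variant_idx, heterogamety)[idx]
        hetero_sex = "female" if heterogamety == "ZW" else "male"
        weights = np.where(sexes == hetero_sex, 1.0, 2.0)
    dose = np.where(ok, calls, 0.0) * (weights[:, None] / 2.0)
    denom = (ok * weights[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(denom > 0, dose.sum(axis=0) / denom, np.nan)
    n_chrom = float(denom[denom > 0].mean()) if (denom > 0).any() else 0.0
    return freqs, n_chrom


# ---------------------------------------------------------------------------
# moment estimator
# ---------------------------------------------------------------------------

def estimate_tau_moments(pop_freqs: np.ndarray, ancestral_freqs: np.ndarray,
                         n_chrom: float, population: str = "",
                         marker_class: str = "autosomal") -> TauEstimate:
    """Moment estimator of the drift branch length from allele frequencies.

    Per SNP, [(p_hat - pi)^2 - p_hat(1 - p_hat)/(n_chrom - 1)] / (pi(1 - pi))
    estimates the standardised drift variance F (the noise term removes the
    binomial sampling variance on n_chrom sampled chromosomes); its mean is
    mapped to the diffusion time scale via tau = -log(1 - F), exact for pure
    Wright-Fisher drift where F = 1 - e^{-tau}.  SNPs with pi in {0, 1} are
    excluded.  Floored at zero.
    """
    p = np.asarray(pop_freqs, dtype=float)
    pi = np.asarray(ancestral_freqs, dtype=float)
    if p.shape != pi.shape:
        raise ValueError("pop_freqs and ancestral_freqs differ in length")
    if n_chrom < 2:
        raise ValueError("need n_chrom >= 2")
    ok = np.isfinite(p) & np.isfinite(pi) & (pi > 0) & (pi < 1)
    p, pi = p[ok], pi[ok]
    if p.size == 0:
        raise ValueError("no usable SNPs (all ancestral frequencies fixed)")
    if p.size < 100:
        warnings.warn(f"only {p.size} usable SNPs; tau estimate will be noisy")
    per_snp = ((p - pi) ** 2 - p * (1 - p) / (n_chrom - 1)) / (pi * (1 - pi))
    f_hat = float(per_snp.mean())
    se_f = float(per_snp.std(ddof=1) / np.sqrt(per_snp.size)) if per_snp.size > 1 else 0.0
    f_hat = min(max(f_hat, 0.0), 0.999999)
    tau = -np.log1p(-f_hat)
    se = se_f / max(1.0 - f_hat, 1e-6)       # delta method through -log(1-F)
    return TauEstimate(population=population, marker_class=marker_class,
                       tau=float(tau), se=float(se), method="moments",
                       n_snps=int(p.size))


# ---------------------------------------------------------------------------
# hierarchical Bayesian estimator (truncated-normal drift approximation)
# ---------------------------------------------------------------------------

def _tn_logpdf(x, mu, var):
    """Log density of Normal(mu, var) truncated to [0, 1]."""
    sd = np.sqrt(var)
    z = (x - mu) / sd
    norm = ndtr((1 - mu) / sd) - ndtr(-mu / sd)
    return -0.5 * z * z - np.log(sd) - np.log(np.maximum(norm, 1e-300))


def _binom_loglik(x, n, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return x * np.log(p) + (n - x) * np.log1p(-p)


@dataclass
class MCMCResult:
    tau_mean: np.ndarray          # per population
    tau_sd: np.ndarray
    samples: np.ndarray           # (n_kept, n_pops)
    acceptance: dict
    converged: bool


def estimate_tau_mcmc(counts: np.ndarray, n_chrom: np.ndarray,
                      schedule: MCMCSchedule | None = None,
                      seed: int | None = None,
                      populations: list[str] | None = None,
                      marker_class: str = "autosomal"
                      ) -> tuple[list[TauEstimate], MCMCResult]:
    """Posterior tau per population under the hierarchical drift model.

    Model: observed alt counts x_jl ~ Binomial(n_j, p_jl); latent population
    frequencies p_jl ~ TruncNormal(pi_l, tau_j pi_l (1 - pi_l)) on [0, 1];
    ancestral pi_l ~ Uniform(0, 1); log tau_j ~ Uniform (log-uniform prior).
    Random-walk Metropolis with pilot-run step adaptation targeting
    acceptance in (0.25, 0.45); populations share pi (star tree).
    """
    if schedule is None:
        schedule = MCMCSchedule()
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need counts for >= 2 populations sharing ancestry")
    n_pops, n_snps = counts.shape
    n_chrom = np.broadcast_to(np.asarray(n_chrom, dtype=float).reshape(-1, 1),
                              counts.shape).copy()
    rng = np.random.default_rng(seed)

    p = np.clip(counts / n_chrom, 0.02, 0.98)
    pi = np.clip(p.mean(axis=0), 0.02, 0.98)
    log_tau = np.full(n_pops, np.log(0.05))
    step_p, step_pi = 0.05, 0.05
    step_tau = np.full(n_pops, 0.3)
    log_tau_bounds = (np.log(1e-5), np.log(10.0))

    def var_of(lt, pivec):
        return np.exp(lt)[:, None] * (pivec * (1 - pivec))[None, :]

    def run(n_iter, collect=False, adapt_iv=None):
        nonlocal p, pi, log_tau
        acc = {"p": 0, "pi": 0, "tau": 0}
        tot = {"p": 0, "pi": 0, "tau": 0}
        kept = []
        for it in range(n_iter):
            # latent frequencies
            prop = p + rng.normal(0, step_p, size=p.shape)
            ok = (prop > 0) & (prop < 1)
            var = var_of(log_tau, pi)
            logr = np.where(
                ok,
                _binom_loglik(counts, n_chrom, prop) - _binom_loglik(counts, n_chrom, p)
                + _tn_logpdf(prop, pi[None, :], var) - _tn_logpdf(p, pi[None, :], var),
                -np.inf)
            take = np.log(rng.random(p.shape)) < logr
            p = np.where(take, prop, p)
            acc["p"] += int(take.sum())
            tot["p"] += take.size
            # ancestral frequencies
            prop_pi = pi + rng.normal(0, step_pi, size=pi.shape)
            okp = (prop_pi > 0) & (prop_pi < 1)
            var_new = var_of(log_tau, np.where(okp, prop_pi, pi))
            logr_pi = np.where(
                okp,
                (_tn_logpdf(p, prop_pi[None, :], var_new)
                 - _tn_logpdf(p, pi[None, :], var_of(log_tau, pi))).sum(axis=0),
                -np.inf)
            take_pi = np.log(rng.random(pi.shape)) < logr_pi
            pi = np.where(take_pi, prop_pi, pi)
            acc["pi"] += int(take_pi.sum())
            tot["pi"] += take_pi.size
            # branch lengths
            prop_lt = log_tau + rng.normal(0, step_tau)
            okt = (prop_lt > log_tau_bounds[0]) & (prop_lt < log_tau_bounds[1])
            logr_t = np.where(
                okt,
                (_tn_logpdf(p, pi[None, :], var_of(prop_lt, pi))
                 - _tn_logpdf(p, pi[None, :], var_of(log_tau, pi))).sum(axis=1),
                -np.inf)
            take_t = np.log(rng.random(log_tau.shape)) < logr_t
            log_tau = np.where(take_t, prop_lt, log_tau)
            acc["tau"] += int(take_t.sum())
            tot["tau"] += take_t.size
            if collect and it >= schedule.burn_in and (it - schedule.burn_in) \
                    % schedule.thin == 0:
                kept.append(np.exp(log_tau).copy())
        rates = {k: acc[k] / max(tot[k], 1) for k in acc}
        return rates, kept

    converged = False
    for _ in range(schedule.pilot_runs):  # pilot step-size adaptation
        rates, _ = run(schedule.pilot_iters)
        in_band = {k: 0.25 <= v <= 0.45 for k, v in rates.items()}
        step_p *= 1.3 if rates["p"] > 0.45 else (0.7 if rates["p"] < 0.25 else 1.0)
        step_pi *= 1.3 if rates["pi"] > 0.45 else (0.7 if rates["pi"] < 0.25 else 1.0)
        if rates["tau"] > 0.45:
            step_tau *= 1.3
        elif rates["tau"] < 0.25:
            step_tau *= 0.7
        if all(in_band.values()):
            converged = True
    if not converged:
        warnings.warn("pilot acceptance did not settle in (0.25, 0.45); "
                      "results may mix poorly")

    rates, kept = run(schedule.iters, collect=True)
    samples = np.array(kept)
    tau_mean = samples.mean(axis=0)
    tau_sd = samples.std(axis=0, ddof=1)
    pops = populations or [f"pop{i + 1}" for i in range(n_pops)]
    ests = [TauEstimate(population=pops[j], marker_class=marker_class,
                        tau=float(tau_mean[j]), se=float(tau_sd[j]),
                        method="mcmc", n_snps=n_snps)
            for j in range(n_pops)]
    return ests, MCMCResult(tau_mean=tau_mean, tau_sd=tau_sd, samples=samples,
                            acceptance=rates, converged=converged)


# ---------------------------------------------------------------------------
# pseudo-replication
# ---------------------------------------------------------------------------

def pseudo_replicate_esr(matrix: GenotypeMatrix,
                         populations: list[str] | None = None,
                         config: ESRConfig | None = None,
                         ancestral_freqs: np.ndarray | None = None
                         ) -> dict[str, ESREstimate]:
    """Replicate SNP-panel resampling of the ESR for each population.

    Each replicate draws a seeded panel of autosomal and sex-linked SNPs
    (with replacement when the matrix holds fewer than requested, logged),
    estimates tau for both marker classes and converts to epsilon.
    ``ancestral_freqs`` (aligned with matrix variants) serves as the
    reference pi; when absent, the across-population pooled mean frequency
    is used, which requires at least two populations.
    """
    if config is None:
        config = ESRConfig()
    if populations is None:
        populations = matrix.populations
    hetero = config.heterogamety
    if hetero == "auto":
        hetero = _infer_heterogamety(matrix)
    auto_idx = np.flatnonzero(~matrix.sex_linked_mask)
    sex_idx = np.flatnonzero(matrix.sex_linked_mask)
    if sex_idx.size == 0:
        raise ValueError("no sex-linked SNPs in the matrix")
    if ancestral_freqs is None and len(matrix.populations) < 2:
        raise ValueError("pooled ancestral frequencies require >= 2 populations; "
                         "pass ancestral_freqs for a single population")
    rng = np.random.default_rng(config.seed)

    def draw(pool, k):
        if pool.size >= k:
            return rng.choice(pool, size=k, replace=False)
        warnings.warn(f"only {pool.size} SNPs available for a panel of {k}; "
                      "sampling with replacement")
        return rng.choice(pool, size=k, replace=True)

    out = {}
    pop_seeds = {pop: rng.integers(0, 2 ** 31) for pop in populations}
    panels = [(draw(auto_idx, config.n_autosomal_snps),
               draw(sex_idx, config.n_sex_snps))
              for _ in range(config.n_replicates)]
    for pop in populations:
        eps_vals = np.empty(config.n_replicates)
        ta_vals = np.empty(config.n_replicates)
        tx_vals = np.empty(config.n_replicates)
        for r, (panel_a, panel_x) in enumerate(panels):
            taus = {}
            for cls, panel, is_sex in (("autosomal", panel_a, False),
                                       ("sex_linked", panel_x, True)):
                freqs, n_chrom = class_frequencies(matrix, pop, panel, is_sex, hetero)
                if ancestral_freqs is not None:
                    pi = np.asarray(ancestral_freqs, dtype=float)[panel]
                else:
                    pi = np.nanmean(np.stack(
                        [class_frequencies(matrix, q, panel, is_sex, hetero)[0]
                         for q in matrix.populations]), axis=0)
                if config.method == "mcmc":
                    counts = np.round(np.stack(
                        [class_frequencies(matrix, q, panel, is_sex, hetero)[0]
                         for q in matrix.populations]) * n_chrom)
                    ests, _ = estimate_tau_mcmc(
                        counts, n_chrom=np.full(len(matrix.populations), n_chrom),
                        schedule=config.mcmc,
                        seed=int((pop_seeds[pop] + r) % 2 ** 31),
                        populations=matrix.populations, marker_class=cls)
                    taus[cls] = next(e for e in ests if e.population == pop)
                else:
                    taus[cls] = estimate_tau_moments(freqs, pi, n_chrom,
                                                     population=pop,
                                                     marker_class=cls)
            ta_vals[r] = taus["autosomal"].tau
            tx_vals[r] = taus["sex_linked"].tau
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                eps_vals[r] = esr_from_tau(tx_vals[r], max(ta_vals[r], 1e-9))
        out[pop] = ESREstimate(population=pop, epsilon=float(eps_vals.mean()),
                               replicate_values=eps_vals,
                               n_replicates=config.n_replicates,
                               replicate_tau_auto=ta_vals,
                               replicate_tau_sex=tx_vals,
                               heterogamety=hetero)
    return out


def esr_table(estimates: dict[str, ESREstimate]) -> pd.DataFrame:
    """Long-form per-replicate table (boxplot-ready)."""
    rows = []
    for pop, est in estimates.items():
        for r in range(est.n_replicates):
            rows.append({"population": pop, "replicate": r,
                         "tau_auto": est.replicate_tau_auto[r],
                         "tau_sex": est.replicate_tau_sex[r],
                         "epsilon": est.replicate_values[r]})
    return pd.DataFrame(rows)


def esr_summary(estimates: dict[str, ESREstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "population": pop,
        "epsilon_mean": est.epsilon,
        "epsilon_sd": float(est.replicate_values.std(ddof=1))
        if est.n_replicates > 1 else 0.0,
        "n_replicates": est.n_replicates,
        "heterogamety": est.heterogamety,
        "interpretation": est.interpretation,
    } for pop, est in estimates.items()])
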