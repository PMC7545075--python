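"""Ground-truth validation scenarios for the pipeline's estimators.

These functions define the package's standard recovery experiments on the
bundled Wright-Fisher simulator: each simulates a demography with known
truth and runs the corresponding estimator.  They are used by the test
suite and the reproduction script.

The ESR scenario pseudo-replicates across independent simulated datasets
(one seeded SNP panel per dataset).  Panels resampled from a single genome
share that genome's drift realisation — linked SNPs are correlated over a
map scale of roughly 1/t Morgans — so replicate datasets, not replicate
panels, are what average away simulation noise.  The genome emulates a
chicken-like map: five 100-Mb autosomes and an 80-Mb sex chromosome at
3 cM/Mb.  Sites fixed by drift are retained (no array ascertainment)
because the tau estimator references the known ancestral frequencies;
conditioning sites on final-sample segregation would bias the contrast.
"""

from __future__ import annotations

import warnings

import numpy as np

from .diversity import fst_weir_cockerham
from .esr import ESRConfig, pseudo_replicate_esr
from .ne import contemporary_ne
from .simulate import SimConfig, simulate


def esr_recovery(n_females: int, n_males: int, sex_chrom: str = "Z",
                 n_replicates: int = 10, generations: int = 50,
                 seed: int = 0) -> dict:
    """Mean ESR over replicate two-sex WF datasets with known sex ratio.

    Each replicate simulates 5,000 autosomal + 5,000 sex-linked SNPs for
    ``generations`` from a common ancestor (ancestral frequencies
    Uniform(0.05, 0.95)) and runs the ESR stage (moment tau estimates
    against the true ancestral frequencies, converted by the printed
    formula).  Under XY semantics the formula's output is the proportion
    of females; the balanced case gives 0.5 under either system.
    """
    rng = np.random.default_rng(seed)
    eps, tau_a, tau_x = [], [], []
    for r in range(n_replicates):
        cfg = SimConfig(seed=int(rng.integers(0, 2 ** 31)),
                        n_females=n_females, n_males=n_males,
                        generations=generations, n_autosomes=5,
                        snps_per_chrom=1000, chrom_length_bp=100_000_000,
                        recomb_cm_per_mb=3.0, sex_chrom=sex_chrom,
                        snps_on_sex_chrom=5000, sex_chrom_length_bp=80_000_000,
                        drop_fixed=False, track_pedigree=False)
        matrix, truth = simulate(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pseudo_replicate_esr(
                matrix, config=ESRConfig(n_replicates=1,
                                         seed=int(rng.integers(0, 2 ** 31))),
                ancestral_freqs=truth.ancestral_freqs)
        est = res["pop1"]
        eps.append(est.replicate_values[0])
        tau_a.append(est.replicate_tau_auto[0])
        tau_x.append(est.replicate_tau_sex[0])
    return {"epsilon_mean": float(np.mean(eps)),
            "epsilon_values": np.array(eps),
            "tau_auto_mean": float(np.mean(tau_a)),
            "tau_sex_mean": float(np.mean(tau_x)),
            "true_epsilon": n_females / (n_females + n_males),
            "n_replicates": n_replicates}


def fst_drift_recovery(ne: int = 100, t: int = 20, n_loci: int = 5000,
                       n_seeds: int = 10, seed: int = 0) -> dict:
    """Median Weir-Cockerham FST across replicate two-population divergences."""
    rng = np.random.default_rng(seed)
    half = ne // 2
    ests = []
    for _ in range(n_seeds):
        cfg = SimConfig(seed=int(rng.integers(0, 2 ** 31)), n_populations=2,
                        n_females=half, n_males=ne - half, generations=t,
                        n_autosomes=10, snps_per_chrom=n_loci // 10,
                        chrom_length_bp=60_000_000, drop_fixed=False,
                        track_pedigree=False)
        matrix, _ = simulate(cfg)
        ests.append(fst_weir_cockerham(matrix, "pop1", "pop2"))
    from .simulate import expected_fst
    return {"median_fst": float(np.median(ests)),
            "values": np.array(ests),
            "expected": expected_fst(ne, t)}


def contemporary_ne_recovery(ne: int = 50, n_subsample: int = 40,
                             n_seeds: int = 10, seed: int = 0) -> dict:
    """Median LD-based contemporary Ne across replicate simulations."""
    rng = np.random.default_rng(seed)
    half = ne // 2
    ests = []
    for s in range(n_seeds):
        cfg = SimConfig(seed=int(rng.integers(0, 2 ** 31)), n_females=half,
                        n_males=ne - half, generations=20, n_autosomes=10,
                        snps_per_chrom=150, chrom_length_bp=30_000_000,
                        track_pedigree=False)
        matrix, _ = simulate(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pt = contemporary_ne(matrix, "pop1", n_subsample=n_subsample,
                                 seed=int(rng.integers(0, 2 ** 31)),
                                 max_pairs=20_000)
        ests.append(pt.ne_hat)
    return {"median_ne": float(np.median(ests)), "values": np.array(ests),
            "true_ne": float(ne)}
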