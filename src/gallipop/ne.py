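"""LD-based effective population size.

Historical trajectory: pairwise r-squared binned by recombination fraction c
(a linear physical-to-genetic map, default 1 cM/Mb, capped at c = 0.5) is
inverted through the Sved relation E[r2_adj] = 1 / (alpha + 4 Ne c), giving
Ne(t) = (1/(4 c)) (1/E[r2_adj] - alpha) at t = 1/(2 c) generations ago.

Contemporary point estimate: at effectively unlinked loci (different
chromosomes, or c >= 0.1), E[r2] ~ 1/(3 Ne) + 1/S for S sampled diploids
with EM-based unphased r-squared, so Ne_hat = 1 / (3 (mean r2 - 1/S)).
Numeric parity with the dedicated tools' extra bias corrections is not
claimed; the estimators here are the standard closed-form inversions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .ld import intra_chrom_pairs, pairwise_r2


def bp_to_c(dist_bp: np.ndarray, rate_cm_per_mb: float = 1.0) -> np.ndarray:
    """Linear map from physical distance to recombination fraction, capped at 0.5."""
    c = np.asarray(dist_bp, dtype=float) * rate_cm_per_mb * 1e-8
    return np.minimum(c, 0.5)


def adjust_r2_for_sample_size(r2, n_individuals: int):
    """Subtract the unphased sampling inflation 1/n; floor at 0 with a flag.

    Returns ``(adjusted, floored)`` where ``floored`` marks entries clipped
    at zero (their raw correlation was below sampling noise).
    """
    if n_individuals < 2:
        raise ValueError("need n >= 2 individuals")
    r2 = np.asarray(r2, dtype=float)
    adj = r2 - 1.0 / n_individuals
    floored = adj <= 0
    out = np.where(floored, 0.0, adj)
    if np.isscalar(r2) or out.ndim == 0:
        return float(out), bool(floored)
    return out, floored


@dataclass
class NeTrajectory:
    population: str
    generations_ago: np.ndarray
    ne: np.ndarray
    c_bin: np.ndarray
    n_pairs: np.ndarray
    masked: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "population": self.population, "t": self.generations_ago,
            "ne": self.ne, "c": self.c_bin, "n_pairs": self.n_pairs,
            "masked": self.masked,
        })


@dataclass
class NePointEstimate:
    population: str
    ne_hat: float            # inf when mean r2 <= 1/S (consistent with infinite Ne)
    n_samples_used: int
    mean_adjusted_r2: float
    n_pairs: int
    defined: bool = True


def historical_ne(r2: np.ndarray, dist_bp: np.ndarray,
                  n_individuals: int | None = None,
                  rate_cm_per_mb: float = 1.0, n_bins: int = 20,
                  min_pairs_per_bin: int = 10, alpha: float = 1.0,
                  population: str = "") -> NeTrajectory:
    """Invert binned LD against recombination distance into an Ne trajectory.

    ``n_individuals`` triggers the 1/n sample-size adjustment; pass ``None``
    when r2 is already adjusted.  ``alpha`` = 1 for the drift-only Sved
    relation (2.2 for the mutation-adjusted variant).
    """
    r2 = np.asarray(r2, dtype=float)
    dist_bp = np.asarray(dist_bp)
    ok = ~np.isnan(r2)
    r2, dist_bp = r2[ok], dist_bp[ok]
    if r2.size == 0:
        raise ValueError("no usable pairs")
    if n_individuals is not None:
        r2, _ = adjust_r2_for_sample_size(r2, n_individuals)
    c = bp_to_c(dist_bp, rate_cm_per_mb)
    edges = np.linspace(0, c.max(), n_bins + 1)
    which = np.clip(np.digitize(c, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    mean_r2 = np.bincount(which, weights=r2, minlength=n_bins) / np.maximum(counts, 1)
    cbar = np.bincount(which, weights=c, minlength=n_bins) / np.maximum(counts, 1)
    masked = (counts < min_pairs_per_bin) | (cbar <= 0) | (mean_r2 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ne = (1.0 / (4.0 * cbar)) * (1.0 / mean_r2 - alpha)
        t = 1.0 / (2.0 * cbar)
    ne = np.where(masked, np.nan, ne)
    if np.any(~masked & (ne <= 0)):
        warnings.warn("some bins hit the Ne <= 0 boundary (E[r2_adj] >= 1/alpha)")
    keep = counts > 0
    return NeTrajectory(population=population, generations_ago=t[keep],
                        ne=ne[keep], c_bin=cbar[keep], n_pairs=counts[keep],
                        masked=masked[keep])


def _unlinked_pairs(matrix: GenotypeMatrix, min_c: float,
                    rate_cm_per_mb: float, max_pairs: int, rng
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sampled variant index pairs on different chromosomes or with c >= min_c."""
    auto = np.flatnonzero(~matrix.sex_linked_mask)
    chroms = matrix.chroms[auto]
    pos = matrix.positions[auto]
    m = auto.size
    if m < 2:
        raise ValueError("need at least two autosomal variants")
    # rejection-sample random pairs; unlinked pairs dominate with many chromosomes
    want = max_pairs
    ia = rng.integers(0, m, size=4 * want)
    ib = rng.integers(0, m, size=4 * want)
    keep = ia < ib
    ia, ib = ia[keep], ib[keep]
    same = chroms[ia] == chroms[ib]
    c = bp_to_c(np.abs(pos[ib] - pos[ia]), rate_cm_per_mb)
    eligible = ~same | (c >= min_c)
    ia, ib = ia[eligible][:want], ib[eligible][:want]
    if ia.size == 0:
        raise ValueError("no eligible unlinked pairs")
    return auto[ia], auto[ib]


def contemporary_ne(matrix: GenotypeMatrix, population: str,
                    n_subsample: int = 40, seed: int | None = None,
                    min_c: float = 0.1, rate_cm_per_mb: float = 1.0,
                    max_pairs: int = 50_000) -> NePointEstimate:
    """Unlinked-locus LD estimate of contemporary Ne for one population.

    Individuals are subsampled (seeded) to ``n_subsample`` when the
    population is larger; the estimator uses S = number actually used.
    """
    rng = np.random.default_rng(seed)
    idx = matrix.pop_indices(population)
    if idx.size < 2:
        raise ValueError("need at least two individuals")
    if idx.size > n_subsample:
        idx = np.sort(rng.choice(idx, size=n_subsample, replace=False))
    s = idx.size
    ia, ib = _unlinked_pairs(matrix, min_c, rate_cm_per_mb, max_pairs, rng)
    r2 = pairwise_r2(matrix.calls[idx], ia, ib)
    r2 = r2[~np.isnan(r2)]
    if r2.size == 0:
        raise ValueError("no polymorphic unlinked pairs in the subsample")
    mean_adj = float(r2.mean() - 1.0 / s)
    if mean_adj <= 0:
        warnings.warn(f"mean r2 <= 1/S for {population!r}: Ne undefined "
                      "(consistent with infinite Ne)")
        return NePointEstimate(population=population, ne_hat=np.inf,
                               n_samples_used=s, mean_adjusted_r2=mean_adj,
                               n_pairs=int(r2.size), defined=False)
    return NePointEstimate(population=population, ne_hat=1.0 / (3.0 * mean_adj),
                           n_samples_used=s, mean_adjusted_r2=mean_adj,
                           n_pairs=int(r2.size), defined=True)


def ld_pairs_for_ne(matrix: GenotypeMatrix, population: str,
                    n_subsample: int = 40, seed: int | None = None,
                    max_dist_bp: int = 10_000_000
                    ) -> tuple[np.ndarray, np.ndarray, int]:
    """Pairwise (r2, dist_bp) on a seeded subsample, for historical_ne."""
    rng = np.random.default_rng(seed)
    idx = matrix.pop_indices(population)
    if idx.size > n_subsample:
        idx = np.sort(rng.choice(idx, size=n_subsample, replace=False))
    ia, ib, dist = intra_chrom_pairs(matrix, max_dist_bp)
    if ia.size == 0:
        raise ValueError("no eligible pairs")
    r2 = pairwise_r2(matrix.calls[idx], ia, ib)
    return r2, dist, idx.size
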