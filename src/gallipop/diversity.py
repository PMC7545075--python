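"""Per-population heterozygosity, nucleotide diversity, and pairwise FST.

Observed heterozygosity is the per-individual fraction of heterozygous calls
among non-missing loci; expected heterozygosity uses the small-sample
unbiased per-locus estimator 2p(1-p) * n_al/(n_al - 1) on the allele basis
(n_al = 2 x non-missing genotypes).  Nucleotide diversity over ascertained
SNP sites is the mean pairwise difference n_ref * n_alt / C(N, 2) per site.
Pairwise FST is the full two-population Weir & Cockerham (1984) estimator
with the a/b/c variance components, accumulated as sum(a)/sum(a+b+c); the
estimate is reported as computed, including small negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class DiversitySummary:
    population: str
    ho_mean: float
    ho_sd: float
    he_mean: float
    he_sd_snps: float   # sd over SNPs of the per-locus expected heterozygosity
    pi_mean: float
    pi_sd: float
    n_samples: int


@dataclass
class FstMatrix:
    populations: list[str]
    values: np.ndarray   # symmetric, zero diagonal
    levels: list[list[str]]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.populations):
            for j, b in enumerate(self.populations):
                if j > i:
                    rows.append({"pop_a": a, "pop_b": b,
                                 "fst": self.values[i, j],
                                 "level": self.levels[i][j]})
        return pd.DataFrame(rows)

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations,
                            columns=self.populations)


def observed_heterozygosity(matrix: GenotypeMatrix, sample: int | str) -> float:
    """Ho for one individual: n_het / n_non_missing."""
    i = matrix.sample_index(sample) if isinstance(sample, str) else sample
    row = matrix.calls[i]
    ok = row != MISSING
    if not ok.any():
        raise ValueError(f"sample {sample!r} has no non-missing calls")
    return float((row[ok] == 1).sum() / ok.sum())


def _pop_calls(matrix: GenotypeMatrix, population: str) -> np.ndarray:
    return matrix.calls[matrix.pop_indices(population)]


def _per_site_unbiased_het(calls: np.ndarray) -> np.ndarray:
    """2p(1-p) * N/(N-1) per site on the allele-count basis N; NaN where N < 2."""
    ok = calls != MISSING
    n_al = 2 * ok.sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_al > 0, alt / n_al, np.nan)
        het = 2 * p * (1 - p) * n_al / np.maximum(n_al - 1, 1)
    return np.where(n_al >= 2, het, np.nan)


def expected_heterozygosity(matrix: GenotypeMatrix, population: str) -> float:
    """He: per-SNP unbiased 2p(1-p), averaged over SNPs with data."""
    idx = matrix.pop_indices(population)
    if idx.size < 2:
        raise ValueError(f"population {population!r} needs >= 2 samples")
    het = _per_site_unbiased_het(matrix.calls[idx])
    het = het[~np.isnan(het)]
    return float(het.mean()) if het.size else 0.0


def nucleotide_diversity(matrix: GenotypeMatrix, population: str
                         ) -> tuple[np.ndarray, float]:
    """Per-site pi = n_ref*n_alt/C(N,2) and its mean over usable sites.

    Sites with fewer than two non-missing alleles are NaN in the per-site
    vector and excluded from the mean (SNP-ascertained pi, not per-bp).
    """
    idx = matrix.pop_indices(population)
    if idx.size < 2:
        raise ValueError(f"population {population!r} needs >= 2 samples")
    calls = matrix.calls[idx]
    ok = calls != MISSING
    n_al = 2 * ok.sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    ref = n_al - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n_al >= 2, ref * alt / (n_al * (n_al - 1) / 2.0), np.nan)
    valid = pi[~np.isnan(pi)]
    if valid.size == 0:
        raise ValueError("no usable sites")
    return pi, float(valid.mean())


def diversity_summary(matrix: GenotypeMatrix, population: str) -> DiversitySummary:
    idx = matrix.pop_indices(population)
    ho = np.array([observed_heterozygosity(matrix, int(i)) for i in idx])
    het = _per_site_unbiased_het(matrix.calls[idx])
    het = het[~np.isnan(het)]
    pi, pi_mean = nucleotide_diversity(matrix, population)
    pi_valid = pi[~np.isnan(pi)]
    return DiversitySummary(
        population=population,
        ho_mean=float(ho.mean()), ho_sd=float(ho.std(ddof=1)) if ho.size > 1 else 0.0,
        he_mean=float(het.mean()) if het.size else 0.0,
        he_sd_snps=float(het.std(ddof=1)) if het.size > 1 else 0.0,
        pi_mean=pi_mean, pi_sd=float(pi_valid.std(ddof=1)) if pi_valid.size > 1 else 0.0,
        n_samples=int(idx.size),
    )


def diversity_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    return pd.DataFrame([vars(diversity_summary(matrix, p))
                         for p in matrix.populations])


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(callsA: np.ndarray, callsB: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 a, b, c for two populations plus a usable-locus mask."""
    r = 2.0
    comps = []
    for calls in (callsA, callsB):
        ok = calls != MISSING
        n = ok.sum(axis=0).astype(float)                      # genotyped individuals
        alt = np.where(ok, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, (np.where(ok, calls, -9) == 1).sum(axis=0) / np.maximum(n, 1),
                     np.nan)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps

    usable = (n1 >= 1) & (n2 >= 1)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    # loci monomorphic across both samples carry no information
    poly = usable & (pbar > 0) & (pbar < 1) & (nbar > 1) & (nc > 0)
    return a, b, c, poly


def fst_weir_cockerham(matrix: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Multi-locus WC84 estimate sum(a) / sum(a+b+c); may be slightly negative."""
    callsA = _pop_calls(matrix, pop_a)
    callsB = _pop_calls(matrix, pop_b)
    a, b, c, ok = _wc_components(callsA, callsB)
    denom = (a + b + c)[ok].sum()
    if not ok.any() or denom == 0:
        raise ValueError(f"no usable loci between {pop_a!r} and {pop_b!r}")
    return float(a[ok].sum() / denom)


def classify_fst(value: float) -> str:
    """Four-level differentiation scale: low <0.05, medium [0.05,0.15),
    high [0.15,0.25], extreme >0.25.  Negative estimates map to low."""
    if not np.isfinite(value):
        raise ValueError("FST value must be finite")
    if value < 0.05:
        return "low"
    if value < 0.15:
        return "medium"
    if value <= 0.25:
        return "high"
    return "extreme"


def fst_matrix(matrix: GenotypeMatrix) -> FstMatrix:
    pops = matrix.populations
    k = len(pops)
    values = np.zeros((k, k))
    levels = [["low"] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            v = fst_weir_cockerham(matrix, pops[i], pops[j])
            values[i, j] = values[j, i] = v
            levels[i][j] = levels[j][i] = classify_fst(v)
    return FstMatrix(populations=pops, values=values, levels=levels)
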