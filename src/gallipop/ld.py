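"""Two-locus linkage disequilibrium from unphased genotypes.

Haplotype frequencies are estimated by the standard two-locus EM algorithm
(maximum-likelihood resolution of the double-heterozygote phase ambiguity,
started from linkage equilibrium), and r-squared follows the classic
haplotype-frequency formula

    r^2 = (p_AB p_ab - p_Ab p_aB)^2 / (P_A P_a P_B P_b).

The decay curve bins all intra-chromosomal pairs closer than ``max_dist_bp``
(default 500 kb) into half-open distance bins (default 5 kb) on a seeded
subsample of individuals (default 7, mirroring small-sample LD surveys).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

EM_TOL = 1e-10
EM_MAX_ITER = 1000


class LDUndefinedError(ValueError):
    """Raised when LD is undefined (a monomorphic locus or zero denominator)."""


@dataclass
class HaplotypeFreqs:
    """Frequencies of the four two-locus haplotypes; A/B = reference alleles."""

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    converged: bool = True
    degenerate: bool = False   # double-het-only table: reported at the LE point

    def __post_init__(self):
        total = self.p_AB + self.p_Ab + self.p_aB + self.p_ab
        if min(self.p_AB, self.p_Ab, self.p_aB, self.p_ab) < -1e-12:
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB


def genotype_pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 table of joint dosage counts, rows = locus 1; missing pairs dropped."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    code = g1[ok] * 3 + g2[ok]
    return np.bincount(code, minlength=9).reshape(3, 3)


# E-step bookkeeping: cell (i, j) of the 3x3 table contributes fixed counts
# to haplotypes (h_AB, h_Ab, h_aB, h_ab) except the double heterozygote.
# Index order for the internal vector: [AB, Ab, aB, ab] with a/b = alt.
_FIXED = np.zeros((9, 4))
for _i in range(3):
    for _j in range(3):
        if (_i, _j) == (1, 1):
            continue
        # dosage i at locus 1 = i copies of allele 'a'; unambiguous phase
        n_a, n_b = _i, _j
        hap_a = (0, 1) if n_a == 1 else (n_a // 2, n_a // 2)
        hap_b = (0, 1) if n_b == 1 else (n_b // 2, n_b // 2)
        for k in range(2):
            _FIXED[_i * 3 + _j, hap_a[k] * 2 + hap_b[k]] += 1
del _i, _j


def _em_batch(tables: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EM over a batch of 3x3 tables.

    Returns (freqs (k, 4) in [AB, Ab, aB, ab] order, converged flags,
    degenerate flags).  Monomorphic tables yield NaN rows.
    """
    tables = np.asarray(tables, dtype=float).reshape(-1, 9)
    k = tables.shape[0]
    n = tables.sum(axis=1)
    # allele frequencies (alt) at each locus
    dose1 = tables.reshape(-1, 3, 3).sum(axis=2) @ np.array([0.0, 1.0, 2.0])
    dose2 = tables.reshape(-1, 3, 3).sum(axis=1) @ np.array([0.0, 1.0, 2.0])
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = dose1 / (2 * n)
        pb = dose2 / (2 * n)
    mono = (pa <= 0) | (pa >= 1) | (pb <= 0) | (pb >= 1) | (n == 0)

    fixed = tables @ _FIXED                       # (k, 4) phase-certain haplotypes
    ndh = tables[:, 4]                            # double heterozygotes
    # start at linkage equilibrium
    h = np.stack([(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb], axis=1)
    h = np.where(mono[:, None], np.nan, h)
    converged = np.zeros(k, dtype=bool)
    active = ~mono
    for _ in range(max_iter):
        if not active.any():
            break
        num = h[:, 0] * h[:, 3]                   # AB/ab phase
        den = num + h[:, 1] * h[:, 2]             # + Ab/aB phase
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(den > 0, num / den, 0.5)
        counts = fixed.copy()
        counts[:, 0] += ndh * w
        counts[:, 3] += ndh * w
        counts[:, 1] += ndh * (1 - w)
        counts[:, 2] += ndh * (1 - w)
        h_new = counts / (2 * n)[:, None]
        delta = np.nanmax(np.abs(h_new - h), axis=1)
        h = np.where(active[:, None], h_new, h)
        newly = active & (delta < tol)
        converged |= newly
        active &= ~newly
    degenerate = (~mono) & (fixed.sum(axis=1) == 0)   # only double hets observed
    return h, converged | degenerate, degenerate


def em_haplotype_freqs(counts: np.ndarray) -> HaplotypeFreqs:
    """ML haplotype frequencies from one 3x3 genotype count table.

    The degenerate all-double-heterozygote table has a symmetric likelihood;
    the linkage-equilibrium stationary point (D = 0) is reported and flagged.
    """
    counts = np.asarray(counts)
    if counts.shape != (3, 3):
        raise ValueError("expected a 3x3 genotype count table")
    if counts.sum() < 1:
        raise ValueError("empty count table")
    h, conv, degen = _em_batch(counts[None])
    if np.isnan(h[0]).any():
        raise LDUndefinedError("a locus is monomorphic; LD undefined")
    # internal order [AB, Ab, aB, ab] uses a/b = alt alleles; map to field names
    hAB, hAb, haB, hab = h[0]
    return HaplotypeFreqs(p_AB=float(hAB), p_Ab=float(hAb), p_aB=float(haB),
                          p_ab=float(hab), converged=bool(conv[0]),
                          degenerate=bool(degen[0]))


def em_log_likelihood(counts: np.ndarray, h: HaplotypeFreqs) -> float:
    """Multinomial log-likelihood of a 3x3 table under haplotype frequencies."""
    # field names use A/B = reference; internal order is alt-allele count
    hv = np.array([h.p_AB, h.p_Ab, h.p_aB, h.p_ab])
    probs = np.zeros(9)
    for i in range(3):
        for j in range(3):
            # sum over ordered haplotype pairs whose alt counts add to (i, j)
            for a1 in range(2):
                for b1 in range(2):
                    a2, b2 = i - a1, j - b1
                    if a2 in (0, 1) and b2 in (0, 1):
                        probs[i * 3 + j] += hv[a1 * 2 + b1] * hv[a2 * 2 + b2]
    counts = np.asarray(counts, dtype=float).ravel()
    with np.errstate(divide="ignore"):
        lp = np.log(probs)
    mask = counts > 0
    if np.any(mask & ~np.isfinite(lp)):
        return -np.inf
    return float((counts[mask] * lp[mask]).sum())


def _r2_from_h(h: np.ndarray) -> np.ndarray:
    """Vectorised r^2 from (k, 4) haplotype frequencies [AB, Ab, aB, ab]."""
    pa = h[:, 2] + h[:, 3]
    pb = h[:, 1] + h[:, 3]
    d = h[:, 0] * h[:, 3] - h[:, 1] * h[:, 2]
    denom = pa * (1 - pa) * pb * (1 - pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, d * d / denom, np.nan)


def r2_from_haplotypes(h: HaplotypeFreqs) -> float:
    """r^2 = (p_AB p_ab - p_Ab p_aB)^2 / (P_A P_a P_B P_b)."""
    pA, pB = h.p_A, h.p_B
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        raise LDUndefinedError("zero denominator: a locus is monomorphic")
    d = h.p_AB * h.p_ab - h.p_Ab * h.p_aB
    return float(d * d / denom)


def r2_em(g1: np.ndarray, g2: np.ndarray) -> float:
    """EM-based r^2 between two dosage vectors (missing pairs dropped)."""
    return r2_from_haplotypes(em_haplotype_freqs(genotype_pair_counts(g1, g2)))


def pairwise_r2(calls: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """EM r^2 for many column pairs of a dosage matrix; NaN where undefined."""
    g1 = calls[:, idx_a]
    g2 = calls[:, idx_b]
    ok = (g1 != MISSING) & (g2 != MISSING)
    code = np.where(ok, g1 * 3 + g2, 9)
    k = len(idx_a)
    tables = np.zeros((k, 10))
    for c in range(10):
        tables[:, c] = (code == c).sum(axis=0)
    h, _, _ = _em_batch(tables[:, :9].reshape(-1, 3, 3))
    return _r2_from_h(h)


@dataclass
class LDDecayCurve:
    population: str
    bin_start_bp: np.ndarray
    bin_end_bp: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    seed: int | None = None
    sample_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "population": self.population,
            "bin_start_bp": self.bin_start_bp, "bin_end_bp": self.bin_end_bp,
            "mean_r2": self.mean_r2, "n_pairs": self.n_pairs,
        })


def intra_chrom_pairs(matrix: GenotypeMatrix, max_dist_bp: int,
                      include_sex_linked: bool = False
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All intra-chromosome variant index pairs within max_dist_bp."""
    chroms = matrix.chroms
    pos = matrix.positions
    keep = np.ones(matrix.n_variants, dtype=bool)
    if not include_sex_linked:
        keep &= ~matrix.sex_linked_mask
    ia, ib = [], []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero((chroms == chrom) & keep)
        p = pos[idx]
        hi = np.searchsorted(p, p + max_dist_bp, side="right")
        for k, j in enumerate(idx):
            if hi[k] > k + 1:
                ia.append(np.full(hi[k] - k - 1, j))
                ib.append(idx[k + 1:hi[k]])
    if not ia:
        return (np.empty(0, dtype=int),) * 3
    ia = np.concatenate(ia)
    ib = np.concatenate(ib)
    return ia, ib, pos[ib] - pos[ia]


def ld_decay_curve(matrix: GenotypeMatrix, population: str,
                   max_dist_bp: int = 500_000, bin_bp: int = 5_000,
                   n_subsample: int = 7, seed: int | None = None) -> LDDecayCurve:
    """Binned mean r^2 by physical distance for one population.

    A seeded subsample of ``n_subsample`` individuals is drawn (all are used,
    with a warning, when the population is smaller).  Sex-linked variants are
    excluded (mixed ploidy in the heterogametic sex).  Bins are half-open
    (start, end] of width ``bin_bp`` covering (0, max_dist_bp].
    """
    idx = matrix.pop_indices(population)
    rng = np.random.default_rng(seed)
    if idx.size > n_subsample:
        idx = np.sort(rng.choice(idx, size=n_subsample, replace=False))
    else:
        warnings.warn(f"population {population!r} has only {idx.size} samples; "
                      "using all")
    ia, ib, dist = intra_chrom_pairs(matrix, max_dist_bp)
    if ia.size == 0:
        raise ValueError("no eligible variant pairs")
    r2 = pairwise_r2(matrix.calls[idx], ia, ib)
    ok = ~np.isnan(r2)
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    # half-open (start, end]: distance d falls in bin floor((d-1)/bin_bp)
    which = np.minimum((dist[ok] - 1) // bin_bp, n_bins - 1).astype(int)
    sums = np.bincount(which, weights=r2[ok], minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    starts = np.arange(n_bins, dtype=np.int64) * bin_bp
    return LDDecayCurve(population=population, bin_start_bp=starts,
                        bin_end_bp=starts + bin_bp, mean_r2=mean_r2,
                        n_pairs=counts, seed=seed,
                        sample_ids=[matrix.sample_ids[i] for i in idx])
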