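"""Data model and I/O for multi-population SNP-array genotypes.

The central container is :class:`GenotypeMatrix`: diploid biallelic calls
coded as alt-allele dosage {0, 1, 2} with ``MISSING = -1``, variants sorted
by chromosome and physical position, and per-sample population/sex metadata.
Readers accept VCF (via cyvcf2) and PLINK text (.ped/.map); a minimal VCF
writer supports round-tripping.  Quality control mirrors common SNP-array
practice: minor-allele-frequency, call-rate and exact Hardy-Weinberg filters
applied once to the pooled data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING: int = -1

_SEX_LABELS = {"male", "female", "unknown"}
_PLINK_SEX = {"1": "male", "2": "female"}


def is_sex_chrom(chrom: str) -> bool:
    """True for Z/W/X/Y labels (optionally ``chr``-prefixed), case-insensitive."""
    c = chrom.lower()
    if c.startswith("chr"):
        c = c[3:]
    return c in {"z", "w", "x", "y"}


def _chrom_sort_key(chrom: str):
    c = chrom.lower()
    if c.startswith("chr"):
        c = c[3:]
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


@dataclass(frozen=True)
class Variant:
    """A biallelic marker with 1-based physical coordinates."""

    chrom: str
    pos_bp: int
    ref_allele: str
    alt_allele: str
    id: str = ""
    is_sex_linked: bool | None = None

    def __post_init__(self):
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos_bp}")
        auto = is_sex_chrom(self.chrom)
        if self.is_sex_linked is None:
            object.__setattr__(self, "is_sex_linked", auto)
        elif self.is_sex_linked != auto:
            raise ValueError(
                f"is_sex_linked={self.is_sex_linked} inconsistent with chrom {self.chrom!r}"
            )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    population: str = "pop1"
    sex: str = "unknown"

    def __post_init__(self):
        if self.sex not in _SEX_LABELS:
            raise ValueError(f"sex must be one of {_SEX_LABELS}, got {self.sex!r}")


class GenotypeMatrix:
    """Samples x variants alt-allele dosages with metadata.

    Parameters
    ----------
    variants : sequence of Variant, sorted by chromosome then position
    samples : sequence of SampleRecord with unique sample ids
    calls : int array (n_samples, n_variants) with values in {-1, 0, 1, 2}
    """

    def __init__(self, variants: Sequence[Variant], samples: Sequence[SampleRecord],
                 calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(variants)):
            raise ValueError(
                f"calls shape {calls.shape} != (n_samples={len(samples)}, "
                f"n_variants={len(variants)})")
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("calls must be in {-1, 0, 1, 2}")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids are not unique")
        for a, b in zip(variants, variants[1:]):
            if a.chrom == b.chrom and b.pos_bp <= a.pos_bp:
                raise ValueError(
                    f"positions not strictly increasing on {a.chrom}: "
                    f"{a.pos_bp} then {b.pos_bp}")
        self.variants = list(variants)
        self.samples = list(samples)
        self.calls = calls

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def populations(self) -> list[str]:
        return sorted({s.population for s in self.samples})

    @property
    def sexes(self) -> np.ndarray:
        return np.array([s.sex for s in self.samples])

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos_bp for v in self.variants], dtype=np.int64)

    @property
    def sex_linked_mask(self) -> np.ndarray:
        return np.array([v.is_sex_linked for v in self.variants], dtype=bool)

    def pop_indices(self, population: str) -> np.ndarray:
        idx = np.array([i for i, s in enumerate(self.samples)
                        if s.population == population], dtype=np.intp)
        if idx.size == 0:
            raise KeyError(f"no samples in population {population!r}")
        return idx

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def subset(self, sample_idx: Iterable[int] | None = None,
               variant_idx: Iterable[int] | None = None) -> "GenotypeMatrix":
        si = (np.arange(self.n_samples) if sample_idx is None
              else np.asarray(list(sample_idx), dtype=np.intp))
        vi = (np.arange(self.n_variants) if variant_idx is None
              else np.asarray(list(variant_idx), dtype=np.intp))
        return GenotypeMatrix([self.variants[i] for i in vi],
                              [self.samples[i] for i in si],
                              self.calls[np.ix_(si, vi)])

    def __repr__(self):
        return (f"GenotypeMatrix({self.n_samples} samples x {self.n_variants} variants, "
                f"{len(self.populations)} populations)")


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def allele_frequency(matrix: GenotypeMatrix, variant_index: int,
                     sample_subset: Iterable[int] | None = None) -> float:
    """Alt-allele frequency at one variant: sum(dosage) / (2 * n non-missing)."""
    col = matrix.calls[:, variant_index]
    if sample_subset is not None:
        col = col[np.asarray(list(sample_subset))]
    ok = col != MISSING
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"no data at variant index {variant_index}")
    return float(col[ok].sum()) / (2.0 * n)


def allele_frequencies(calls: np.ndarray) -> np.ndarray:
    """Vectorised alt-allele frequencies per column; NaN where all missing."""
    ok = calls != MISSING
    n = ok.sum(axis=0)
    tot = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, tot / (2.0 * n), np.nan)


def call_rates(calls: np.ndarray) -> np.ndarray:
    return (calls != MISSING).sum(axis=0) / calls.shape[0]


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided conditional exact HWE test on heterozygote counts.

    Given the allele counts, sums the hypergeometric-style probabilities of
    every heterozygote configuration no more probable than the observed one
    (plain p, not mid-p).  Symmetric in the two homozygote counts.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor allele count
    # feasible het counts share the parity of the minor allele count
    hets = np.arange(n_a % 2, n_a + 1, 2)
    # conditional log-probability of h hets given n genotypes and n_a minor alleles
    logp = (hets * np.log(2.0)
            - gammaln((n_a - hets) / 2 + 1) - gammaln(hets + 1)
            - gammaln((2 * n - n_a - hets) / 2 + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-9)].sum()))


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

@dataclass
class QCConfig:
    """Array QC thresholds: MAF >= 0.05, call rate >= 0.90, HWE p >= 1e-6."""

    min_maf: float = 0.05
    min_call_rate: float = 0.90
    hwe_p_floor: float = 1e-6

    def __post_init__(self):
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0 <= self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in [0, 1]")
        if not 0 < self.hwe_p_floor < 1:
            raise ValueError("hwe_p_floor must be in (0, 1)")


@dataclass
class QCReport:
    n_input: int
    n_removed_maf: int
    n_removed_callrate: int
    n_removed_hwe: int
    n_retained: int
    removed_maf_ids: list[str] = field(default_factory=list)
    removed_callrate_ids: list[str] = field(default_factory=list)
    removed_hwe_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        total = (self.n_retained + self.n_removed_maf + self.n_removed_callrate
                 + self.n_removed_hwe)
        if total != self.n_input:
            raise ValueError("QC report counts are inconsistent")

    def to_frame(self) -> pd.DataFrame:
        rows = ([("maf", i) for i in self.removed_maf_ids]
                + [("call_rate", i) for i in self.removed_callrate_ids]
                + [("hwe", i) for i in self.removed_hwe_ids])
        return pd.DataFrame(rows, columns=["filter", "variant_id"])

    def write_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


def apply_qc(matrix: GenotypeMatrix, config: QCConfig | None = None, *,
             per_population: bool = False,
             hwe_on_sex_linked: bool = False) -> tuple[GenotypeMatrix, QCReport]:
    """Filter variants by MAF, call rate and HWE; samples are never removed.

    Removal reasons are assigned with precedence MAF -> call rate -> HWE so
    each dropped variant carries one reason; the retained set itself is
    order-independent.  By default all statistics are pooled across
    populations and sex-linked variants are exempt from the HWE filter
    (hemizygosity in the heterogametic sex violates its assumptions).
    """
    if config is None:
        config = QCConfig()
    if matrix.n_variants == 0:
        raise ValueError("empty matrix")

    def _fail_masks(calls):
        freqs = allele_frequencies(calls)
        maf = np.minimum(freqs, 1 - freqs)
        fail_maf = maf < config.min_maf  # NaN compares False: all-missing -> call rate
        fail_cr = call_rates(calls) < config.min_call_rate
        return fail_maf, fail_cr

    if per_population:
        fail_maf = np.zeros(matrix.n_variants, dtype=bool)
        fail_cr = np.zeros(matrix.n_variants, dtype=bool)
        groups = [matrix.pop_indices(p) for p in matrix.populations]
        for idx in groups:
            fm, fc = _fail_masks(matrix.calls[idx])
            fail_maf |= fm
            fail_cr |= fc
    else:
        groups = [np.arange(matrix.n_samples)]
        fail_maf, fail_cr = _fail_masks(matrix.calls)

    fail_hwe = np.zeros(matrix.n_variants, dtype=bool)
    sex_linked = matrix.sex_linked_mask
    for j in range(matrix.n_variants):
        if sex_linked[j] and not hwe_on_sex_linked:
            continue
        if fail_maf[j] or fail_cr[j]:  # already removed; reason precedence MAF -> CR
            continue
        for idx in groups:
            col = matrix.calls[idx, j]
            counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
            if sum(counts) == 0:
                continue
            if hwe_exact_test(*counts) < config.hwe_p_floor:
                fail_hwe[j] = True
                break

    reason_maf = fail_maf
    reason_cr = fail_cr & ~fail_maf
    reason_hwe = fail_hwe & ~fail_maf & ~fail_cr
    keep = ~(fail_maf | fail_cr | fail_hwe)

    ids = np.array([v.id or f"{v.chrom}:{v.pos_bp}" for v in matrix.variants])
    report = QCReport(
        n_input=matrix.n_variants,
        n_removed_maf=int(reason_maf.sum()),
        n_removed_callrate=int(reason_cr.sum()),
        n_removed_hwe=int(reason_hwe.sum()),
        n_retained=int(keep.sum()),
        removed_maf_ids=list(ids[reason_maf]),
        removed_callrate_ids=list(ids[reason_cr]),
        removed_hwe_ids=list(ids[reason_hwe]),
    )
    return matrix.subset(variant_idx=np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> dict[str, SampleRecord]:
    """TSV with columns sample_id, population[, sex]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("sample sheet needs a 'sample_id' column")
    out = {}
    for _, row in df.iterrows():
        out[row["sample_id"]] = SampleRecord(
            sample_id=row["sample_id"],
            population=row.get("population", "pop1") or "pop1",
            sex=(row.get("sex") or "unknown") if "sex" in df.columns else "unknown",
        )
    return out


def _sorted_matrix(variants, samples, calls_cols):
    order = sorted(range(len(variants)),
                   key=lambda i: (_chrom_sort_key(variants[i].chrom), variants[i].pos_bp))
    calls = np.stack([calls_cols[i] for i in order], axis=1) if variants else \
        np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix([variants[i] for i in order], samples, calls)


def read_vcf(path, sample_sheet=None) -> GenotypeMatrix:
    """Read a VCF with GT fields; non-biallelic records are skipped with a warning."""
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    sheet = {}
    if sample_sheet is not None:
        sheet = sample_sheet if isinstance(sample_sheet, dict) else read_sample_sheet(sample_sheet)
    samples = [sheet.get(s, SampleRecord(sample_id=s)) for s in vcf.samples]

    variants, cols, n_skipped = [], [], 0
    # cyvcf2 gts012 coding: 0=hom ref, 1=het, 2=hom alt, 3=unknown
    dosage_map = np.array([0, 1, 2, MISSING], dtype=np.int8)
    for rec in vcf:
        if len(rec.ALT) != 1 or rec.ALT[0] in (".", "") or len(rec.REF) == 0:
            n_skipped += 1
            continue
        variants.append(Variant(chrom=rec.CHROM, pos_bp=rec.POS, ref_allele=rec.REF,
                                alt_allele=rec.ALT[0], id=rec.ID or f"{rec.CHROM}:{rec.POS}"))
        cols.append(dosage_map[np.asarray(rec.gt_types)])
    vcf.close()
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic record(s) in {path}")
    if not variants:
        raise ValueError(f"no biallelic records in {path}")
    return _sorted_matrix(variants, samples, cols)


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT only) with contig headers."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chrom_max: dict[str, int] = {}
    for v in matrix.variants:
        chrom_max[v.chrom] = max(chrom_max.get(v.chrom, 0), v.pos_bp)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gallipop\n")
        for c, ln in chrom_max.items():
            fh.write(f"##contig=<ID={c},length={ln + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for j, v in enumerate(matrix.variants):
            row = [v.chrom, str(v.pos_bp), v.id or ".", v.ref_allele, v.alt_allele,
                   ".", "PASS", ".", "GT"]
            row += [gt[int(x)] for x in matrix.calls[:, j]]
            fh.write("\t".join(row) + "\n")


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read a PLINK text .ped/.map pair.

    Dosages count the alt allele, defined per marker as the first-seen allele
    that differs from the first-seen (reference) allele; "0 0" is missing.
    """
    map_rows = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"malformed .map line: {line!r}")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    m = len(map_rows)

    samples, geno_rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f".ped line has {len(parts)} fields, expected {6 + 2 * m} "
                    f"for {m} markers")
            fid, iid, _, _, sex_code = parts[:5]
            samples.append(SampleRecord(sample_id=iid, population=fid,
                                        sex=_PLINK_SEX.get(sex_code, "unknown")))
            geno_rows.append(parts[6:])

    ref = [None] * m
    alt = [None] * m
    cols = [np.full(len(samples), MISSING, dtype=np.int8) for _ in range(m)]
    for i, row in enumerate(geno_rows):
        for j in range(m):
            a1, a2 = row[2 * j], row[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            d = 0
            for a in (a1, a2):
                if ref[j] is None:
                    ref[j] = a
                if a != ref[j]:
                    if alt[j] is None:
                        alt[j] = a
                    elif a != alt[j]:
                        raise ValueError(f"marker {map_rows[j][1]} has more than 2 alleles")
                    d += 1
            cols[j][i] = d
    variants = []
    for j, (chrom, mid, pos) in enumerate(map_rows):
        variants.append(Variant(chrom=chrom, pos_bp=pos,
                                ref_allele=ref[j] or "A",
                                alt_allele=alt[j] or ("B" if (ref[j] or "A") != "B" else "C"),
                                id=mid))
    return _sorted_matrix(variants, samples, cols)
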