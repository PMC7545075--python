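"""Runs of homozygosity: sliding-window detection, F_ROH, incidence, islands.

The detector reproduces the scanning-window semantics of the classic
array-based ROH callers: a 50-SNP window slides along each autosome and
"passes" when it holds at most one heterozygote and five missing calls; a
SNP becomes a candidate when at least 5% of the windows overlapping it pass;
maximal candidate runs are split at >1 Mb inter-SNP gaps and filtered by
minimum length (100 kb), SNP count (25) and density (1 SNP / 50 kb).
Because the allowance applies at the window stage, final segments may
contain isolated heterozygous or missing calls — by design.

F_ROH divides the summed segment length by the autosomal map length
(default 952,090 kb, the span typed by a 600K chicken array; recompute from
the input map with :func:`l_auto_from_matrix` when analysing other data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

DEFAULT_L_AUTO_KB = 952_090.0


@dataclass
class ROHParams:
    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    min_length_kb: float = 100.0
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    window_hit_threshold: float = 0.05
    min_snps_per_segment: int = 25

    def __post_init__(self):
        numeric = (self.window_snps, self.min_length_kb, self.min_density_kb_per_snp,
                   self.max_gap_kb, self.min_snps_per_segment)
        if any(v <= 0 for v in numeric):
            raise ValueError("ROH parameters must be positive")
        if self.max_het_per_window < 0 or self.max_missing_per_window < 0:
            raise ValueError("window allowances must be non-negative")
        if not 0 < self.window_hit_threshold <= 1:
            raise ValueError("window_hit_threshold must be in (0, 1]")


@dataclass
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int     # 1-based inclusive
    end_bp: int
    n_snps: int

    def __post_init__(self):
        if self.end_bp < self.start_bp:
            raise ValueError("end_bp < start_bp")

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


@dataclass
class ROHIsland:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_incidence: float
    group: str


def _candidate_snps(het: np.ndarray, mis: np.ndarray, params: ROHParams) -> np.ndarray:
    """Window-stage candidacy per SNP of one chromosome (vectorised)."""
    m = het.size
    w = params.window_snps
    if m < w:
        return np.zeros(m, dtype=bool)
    kern = np.ones(w)
    het_w = np.convolve(het.astype(float), kern, mode="valid")   # windows 0..m-w
    mis_w = np.convolve(mis.astype(float), kern, mode="valid")
    passing = ((het_w <= params.max_het_per_window)
               & (mis_w <= params.max_missing_per_window)).astype(float)
    n_win = passing.size
    cpass = np.concatenate([[0.0], np.cumsum(passing)])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    hits = cpass[hi + 1] - cpass[lo]
    total = (hi - lo + 1).astype(float)
    return hits / total >= params.window_hit_threshold


def _runs_to_segments(sample_id, chrom, pos, cand, params) -> list[ROHSegment]:
    segments = []
    j = 0
    m = cand.size
    max_gap_bp = params.max_gap_kb * 1000.0
    while j < m:
        if not cand[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and cand[k + 1] and (pos[k + 1] - pos[k]) <= max_gap_bp:
            k += 1
        n_snps = k - j + 1
        length_kb = (pos[k] - pos[j] + 1) / 1000.0
        if (length_kb >= params.min_length_kb
                and n_snps >= params.min_snps_per_segment
                and length_kb / n_snps <= params.min_density_kb_per_snp):
            segments.append(ROHSegment(sample_id=sample_id, chrom=chrom,
                                       start_bp=int(pos[j]), end_bp=int(pos[k]),
                                       n_snps=n_snps))
        j = k + 1
    return segments


def detect_roh(matrix: GenotypeMatrix, sample: int | str,
               params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH segments on the autosomes of one individual."""
    if params is None:
        params = ROHParams()
    i = matrix.sample_index(sample) if isinstance(sample, str) else sample
    sid = matrix.samples[i].sample_id
    row = matrix.calls[i]
    chroms = matrix.chroms
    pos = matrix.positions
    auto = ~matrix.sex_linked_mask
    segments = []
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero((chroms == chrom) & auto)
        if sel.size == 0:
            continue
        g = row[sel]
        cand = _candidate_snps(g == 1, g == MISSING, params)
        segments += _runs_to_segments(sid, chrom, pos[sel], cand, params)
    return segments


def detect_roh_all(matrix: GenotypeMatrix, params: ROHParams | None = None
                   ) -> dict[str, list[ROHSegment]]:
    return {s.sample_id: detect_roh(matrix, s.sample_id, params)
            for s in matrix.samples}


def l_auto_from_matrix(matrix: GenotypeMatrix) -> float:
    """Summed autosomal span of typed SNPs, in kb."""
    chroms = matrix.chroms
    pos = matrix.positions
    auto = ~matrix.sex_linked_mask
    total = 0.0
    for chrom in pd.unique(chroms[auto]):
        p = pos[(chroms == chrom) & auto]
        total += (p.max() - p.min() + 1) / 1000.0
    return total


def f_roh(segments: list[ROHSegment], l_auto_kb: float = DEFAULT_L_AUTO_KB) -> float:
    """Genomic inbreeding coefficient: sum of ROH lengths / autosomal length."""
    by_chrom: dict[str, list[ROHSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(f"overlapping segments on {chrom} "
                                 f"({a.start_bp}-{a.end_bp} and {b.start_bp}-{b.end_bp})")
    total_kb = sum(s.length_kb for s in segments)
    value = total_kb / l_auto_kb
    if not 0 <= value <= 1 + 1e-12:
        raise ValueError(f"F_ROH = {value} outside [0, 1]; check l_auto_kb")
    return min(value, 1.0)


def snp_roh_incidence(segments_by_sample: dict[str, list[ROHSegment]],
                      matrix: GenotypeMatrix, group: str) -> pd.DataFrame:
    """Fraction of the group's individuals whose ROH cover each autosomal SNP."""
    members = [matrix.samples[i].sample_id for i in matrix.pop_indices(group)]
    if not members:
        raise ValueError(f"empty group {group!r}")
    auto_idx = np.flatnonzero(~matrix.sex_linked_mask)
    chroms = matrix.chroms[auto_idx]
    pos = matrix.positions[auto_idx]
    counts = np.zeros(auto_idx.size)
    for sid in members:
        for seg in segments_by_sample.get(sid, []):
            sel = (chroms == seg.chrom) & (pos >= seg.start_bp) & (pos <= seg.end_bp)
            counts[sel] += 1
    return pd.DataFrame({"chrom": chroms, "pos_bp": pos,
                         "incidence": counts / len(members)})


def roh_islands(incidence: pd.DataFrame, top_fraction: float = 0.01,
                group: str = "") -> list[ROHIsland]:
    """Merge adjacent top-1%-incidence SNPs into population ROH islands.

    The threshold is the empirical (1 - top_fraction) quantile of per-SNP
    incidence; SNPs at or above it (and above zero) are selected, and runs of
    adjacent selected SNPs on one chromosome become islands.  When all
    incidences are equal the threshold ties with every SNP (degenerate case:
    one island per chromosome).
    """
    if len(incidence) < 100:
        raise ValueError("incidence must cover at least 100 SNPs")
    vals = incidence["incidence"].to_numpy()
    if (vals == 0).all():
        return []
    threshold = float(np.quantile(vals, 1 - top_fraction))
    selected = (vals >= threshold) & (vals > 0)
    islands = []
    chroms = incidence["chrom"].to_numpy()
    pos = incidence["pos_bp"].to_numpy()
    j = 0
    m = selected.size
    while j < m:
        if not selected[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and selected[k + 1] and chroms[k + 1] == chroms[j]:
            k += 1
        islands.append(ROHIsland(chrom=str(chroms[j]), start_bp=int(pos[j]),
                                 end_bp=int(pos[k]), n_snps=k - j + 1,
                                 peak_incidence=float(vals[j:k + 1].max()),
                                 group=group))
        j = k + 1
    return islands


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def segments_to_frame(segments_by_sample: dict[str, list[ROHSegment]],
                      matrix: GenotypeMatrix | None = None) -> pd.DataFrame:
    """PLINK .hom-style table (FID, IID, CHR, POS1, POS2, KB, NSNP)."""
    fid = {}
    if matrix is not None:
        fid = {s.sample_id: s.population for s in matrix.samples}
    rows = []
    for sid, segs in segments_by_sample.items():
        for s in segs:
            rows.append({"FID": fid.get(sid, sid), "IID": sid, "CHR": s.chrom,
                         "POS1": s.start_bp, "POS2": s.end_bp,
                         "KB": s.length_kb, "NSNP": s.n_snps})
    return pd.DataFrame(rows, columns=["FID", "IID", "CHR", "POS1", "POS2", "KB", "NSNP"])


def islands_to_bed(islands: list[ROHIsland]) -> pd.DataFrame:
    """0-based half-open BED conversion of 1-based inclusive islands."""
    return pd.DataFrame([{"chrom": i.chrom, "start": i.start_bp - 1, "end": i.end_bp,
                          "name": f"{i.group}_island" if i.group else "island",
                          "score": i.peak_incidence} for i in islands])
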