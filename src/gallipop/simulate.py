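"""Two-sex Wright-Fisher forward simulator with recorded ground truth.

Simulates one or more populations of constant census size (``n_females``
breeding dams, ``n_males`` breeding sires) diverging independently from a
common ancestral allele-frequency pool.  Autosomes recombine with Poisson
crossover counts on a linear genetic map; an optional sex chromosome follows
ZW (birds: males ZZ, females ZW) or XY transmission.  Hemizygous genotypes
are emitted as homozygous diploid calls, the way SNP arrays report them.

Ground truth (:class:`SimTruth`) records, per population, the census sizes
by sex, the true proportion of females, the autosomal and sex-linked
effective sizes, the divergence time, the pure-drift FST expectation and the
pedigree mean inbreeding per generation, so every downstream estimator can
be judged against known values.

Generation accounting: the binomial founder draw from the ancestral pool is
drift generation 1, followed by ``generations - 1`` rounds of breeding; with
equal sex numbers the founder draw drifts by exactly 1/(2 Ne) so the
closed-form FST expectation holds without an off-by-one.  ``generations=0``
emits founders directly (residual ~1/(2N) founder noise).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleRecord, Variant, write_vcf

__all__ = ["SimConfig", "SimTruth", "PopulationTruth", "simulate", "expected_fst",
           "sex_linked_ne", "write_fixture_suite"]


def expected_fst(ne: float, t: int) -> float:
    """Pure-drift expectation 1 - (1 - 1/(2 Ne))^t."""
    if ne <= 0:
        raise ValueError("ne must be positive")
    if t < 0:
        raise ValueError("t must be non-negative")
    return 1.0 - (1.0 - 1.0 / (2.0 * ne)) ** t


def autosomal_ne(n_f: int, n_m: int) -> float:
    return 4.0 * n_f * n_m / (n_f + n_m)


def sex_linked_ne(n_f: int, n_m: int, system: str) -> float:
    """Effective size of the sex chromosome under XY or ZW heterogamety.

    The homogametic sex carries two copies, the heterogametic one.  For XY
    (homogametic females): Ne_X = 9 Nf Nm / (2 Nf + 4 Nm); ZW mirrors it.
    """
    if system == "X":
        return 9.0 * n_f * n_m / (2.0 * n_f + 4.0 * n_m)
    if system == "Z":
        return 9.0 * n_f * n_m / (2.0 * n_m + 4.0 * n_f)
    raise ValueError(f"unknown sex chromosome system {system!r}")


@dataclass
class SimConfig:
    """Scenario description; ``seed`` is mandatory for reproducibility."""

    seed: int
    n_populations: int = 1
    n_females: int | Sequence[int] = 25
    n_males: int | Sequence[int] = 25
    generations: int = 20
    n_autosomes: int = 5
    snps_per_chrom: int = 500
    chrom_length_bp: int = 50_000_000
    recomb_cm_per_mb: float = 1.0
    sex_chrom: str = "none"          # none | Z (ZW) | X (XY)
    snps_on_sex_chrom: int = 0
    sex_chrom_length_bp: int | None = None
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    mating: str = "random"           # random | half_sib | full_sib
    mutation_rate: float = 0.0
    drop_fixed: bool = True
    track_pedigree: bool = True
    record_heterozygosity: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.sex_chrom not in ("none", "Z", "X"):
            raise ValueError("sex_chrom must be 'none', 'Z' or 'X'")
        if self.mating not in ("random", "half_sib", "full_sib"):
            raise ValueError("unknown mating scheme")
        if self.generations < 0 or self.n_populations < 1:
            raise ValueError("counts must be positive")
        if self.recomb_cm_per_mb < 0 or self.mutation_rate < 0:
            raise ValueError("rates must be non-negative")
        for v in (*self._nf_list(), *self._nm_list()):
            if v < 1:
                raise ValueError("population extinct: need N_f >= 1 and N_m >= 1")
        if self.sex_chrom != "none" and self.snps_on_sex_chrom < 1:
            raise ValueError("sex_chrom set but snps_on_sex_chrom < 1")
        if self.sex_chrom_length_bp is None:
            self.sex_chrom_length_bp = self.chrom_length_bp

    def _aslist(self, v) -> list[int]:
        if np.isscalar(v):
            return [int(v)] * self.n_populations
        v = list(v)
        if len(v) != self.n_populations:
            raise ValueError("per-population size list has wrong length")
        return [int(x) for x in v]

    def _nf_list(self) -> list[int]:
        return self._aslist(self.n_females)

    def _nm_list(self) -> list[int]:
        return self._aslist(self.n_males)


@dataclass
class PopulationTruth:
    population: str
    n_f: int
    n_m: int
    epsilon: float                    # true proportion of females N_f/(N_f+N_m)
    ne_auto: float
    ne_sex: float | None
    t: int
    expected_fst: float
    mean_inbreeding_by_generation: list[float] = field(default_factory=list)
    mean_exp_het_by_generation: list[float] = field(default_factory=list)


@dataclass
class SimTruth:
    populations: list[PopulationTruth]
    ancestral_freqs: np.ndarray       # aligned with emitted variants
    sex_system: str | None
    seed: int
    n_dropped_fixed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "population": p.population, "n_f": p.n_f, "n_m": p.n_m,
            "epsilon": p.epsilon, "ne_auto": p.ne_auto, "ne_sex": p.ne_sex,
            "t": p.t, "expected_fst": p.expected_fst,
            "final_mean_pedigree_f": (p.mean_inbreeding_by_generation[-1]
                                      if p.mean_inbreeding_by_generation else 0.0),
        } for p in self.populations])


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _snp_positions(rng, length_bp: int, m: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length_bp + 1, size=int(m * 1.3) + 8))
    while pos.size < m:  # collisions are rare; top up
        extra = rng.integers(1, length_bp + 1, size=m)
        pos = np.unique(np.concatenate([pos, extra]))
    take = np.sort(rng.choice(pos.size, size=m, replace=False))
    return pos[take]


def _gametes(haps: np.ndarray, parent_idx: np.ndarray, pos: np.ndarray,
             length_bp: int, cm_length: float, rng) -> np.ndarray:
    """One recombinant gamete per entry of ``parent_idx``."""
    n, m = parent_idx.size, pos.size
    out = np.empty((n, m), dtype=np.int8)
    n_xo = rng.poisson(cm_length / 100.0, size=n)
    starts = rng.integers(0, 2, size=n)
    for i in range(n):
        hp = haps[parent_idx[i]]
        if n_xo[i] == 0:
            out[i] = hp[starts[i]]
        else:
            xo = np.sort(rng.integers(1, length_bp + 1, size=n_xo[i]))
            phase = (starts[i] + np.searchsorted(xo, pos)) & 1
            out[i] = np.where(phase == 0, hp[0], hp[1])
    return out


def _choose_parents(rng, n_f, n_m, n_off, mating):
    """Global parent indices (females occupy 0..n_f-1, males n_f..) per offspring."""
    off = np.arange(n_off)
    if mating == "random":
        dams = rng.integers(0, n_f, size=n_off)
        sires = n_f + rng.integers(0, n_m, size=n_off)
    elif mating == "half_sib":
        k = max(1, n_m // 5)  # few sires serve all dams
        dams = rng.integers(0, n_f, size=n_off)
        sires = n_f + rng.integers(0, k, size=n_off)
    else:  # full_sib: fixed dam-sire pairs, offspring stay within the family line
        n_fam = min(n_f, n_m)
        fam = off % n_fam
        dams = fam.copy()
        sires = n_f + fam
    return dams, sires


def _mutate(h: np.ndarray, mu: float, rng) -> None:
    if mu > 0:
        flip = rng.random(h.shape) < mu
        np.bitwise_xor(h, flip.astype(np.int8), out=h)


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Run the simulation and return the final-generation genotypes plus truth."""
    rng = np.random.default_rng(config.seed)
    nf_list, nm_list = config._nf_list(), config._nm_list()
    t = config.generations

    lo, hi = config.ancestral_freq_range
    auto_pos = [_snp_positions(rng, config.chrom_length_bp, config.snps_per_chrom)
                for _ in range(config.n_autosomes)]
    auto_q = [rng.uniform(lo, hi, size=config.snps_per_chrom)
              for _ in range(config.n_autosomes)]
    sex_system = None if config.sex_chrom == "none" else config.sex_chrom
    if sex_system:
        sex_pos = _snp_positions(rng, config.sex_chrom_length_bp, config.snps_on_sex_chrom)
        sex_q = rng.uniform(lo, hi, size=config.snps_on_sex_chrom)
    cm_auto = config.chrom_length_bp / 1e6 * config.recomb_cm_per_mb
    cm_sex = (config.sex_chrom_length_bp / 1e6 * config.recomb_cm_per_mb
              if sex_system else 0.0)

    pop_truths, all_samples, all_auto, all_sex = [], [], [], []
    for ip in range(config.n_populations):
        n_f, n_m = nf_list[ip], nm_list[ip]
        n = n_f + n_m
        name = f"pop{ip + 1}"
        is_female = np.zeros(n, dtype=bool)
        is_female[:n_f] = True

        # founder draw = drift generation 1
        autos = [rng.binomial(1, q, size=(n, 2, q.size)).astype(np.int8)
                 for q in auto_q]
        if sex_system:
            zh = rng.binomial(1, sex_q, size=(n, 2, sex_q.size)).astype(np.int8)
            hetero = is_female if sex_system == "Z" else ~is_female
            zh[hetero, 1] = zh[hetero, 0]  # heterogametic sex: single copy, duplicated
        else:
            zh = None

        kinship = 0.5 * np.eye(n) if config.track_pedigree else None
        f_by_gen, het_by_gen = [0.0], []

        def _record_het():
            ps = np.concatenate([h.mean(axis=(0, 1)) for h in autos])
            het_by_gen.append(float(np.mean(2 * ps * (1 - ps))))

        if config.record_heterozygosity:
            _record_het()

        for _ in range(max(0, t - 1)):
            dams, sires = _choose_parents(rng, n_f, n_m, n, config.mating)
            new_autos = []
            for c in range(config.n_autosomes):
                h0 = _gametes(autos[c], dams, auto_pos[c], config.chrom_length_bp,
                              cm_auto, rng)
                h1 = _gametes(autos[c], sires, auto_pos[c], config.chrom_length_bp,
                              cm_auto, rng)
                _mutate(h0, config.mutation_rate, rng)
                _mutate(h1, config.mutation_rate, rng)
                new_autos.append(np.stack([h0, h1], axis=1))
            if sex_system:
                new_z = np.empty_like(zh)
                if sex_system == "Z":  # sires ZZ recombine; dams pass single Z to sons
                    sire_g = _gametes(zh, sires, sex_pos, config.sex_chrom_length_bp,
                                      cm_sex, rng)
                    _mutate(sire_g, config.mutation_rate, rng)
                    dam_z = zh[dams, 0]
                    sons = ~is_female
                    new_z[sons, 0] = dam_z[sons]
                    new_z[sons, 1] = sire_g[sons]
                    new_z[is_female, 0] = sire_g[is_female]
                    new_z[is_female, 1] = sire_g[is_female]
                else:  # XY: dams XX recombine; sires pass single X to daughters
                    dam_g = _gametes(zh, dams, sex_pos, config.sex_chrom_length_bp,
                                     cm_sex, rng)
                    _mutate(dam_g, config.mutation_rate, rng)
                    sire_x = zh[sires, 0]
                    new_z[is_female, 0] = dam_g[is_female]
                    new_z[is_female, 1] = sire_x[is_female]
                    sons = ~is_female
                    new_z[sons, 0] = dam_g[sons]
                    new_z[sons, 1] = dam_g[sons]
                zh = new_z
            autos = new_autos
            if kinship is not None:
                f_off = kinship[dams, sires]
                k_new = 0.25 * (kinship[np.ix_(dams, dams)] + kinship[np.ix_(dams, sires)]
                                + kinship[np.ix_(sires, dams)] + kinship[np.ix_(sires, sires)])
                np.fill_diagonal(k_new, 0.5 * (1 + f_off))
                kinship = k_new
                f_by_gen.append(float(f_off.mean()))
            if config.record_heterozygosity:
                _record_het()

        ne_a = autosomal_ne(n_f, n_m)
        pop_truths.append(PopulationTruth(
            population=name, n_f=n_f, n_m=n_m,
            epsilon=n_f / (n_f + n_m),
            ne_auto=ne_a,
            ne_sex=sex_linked_ne(n_f, n_m, sex_system) if sex_system else None,
            t=t, expected_fst=expected_fst(ne_a, t),
            mean_inbreeding_by_generation=f_by_gen,
            mean_exp_het_by_generation=het_by_gen,
        ))
        sex_names = np.where(is_female, "female", "male")
        all_samples += [SampleRecord(sample_id=f"{name}_i{j + 1:03d}", population=name,
                                     sex=sex_names[j]) for j in range(n)]
        all_auto.append([h.sum(axis=1, dtype=np.int8) for h in autos])
        all_sex.append(zh.sum(axis=1, dtype=np.int8) if sex_system else None)

    # assemble matrix
    variants, cols, anc = [], [], []
    for c in range(config.n_autosomes):
        chrom = str(c + 1)
        block = np.concatenate([pa[c] for pa in all_auto], axis=0)
        for j, p in enumerate(auto_pos[c]):
            variants.append(Variant(chrom=chrom, pos_bp=int(p), ref_allele="A",
                                    alt_allele="B", id=f"snp_{chrom}_{p}"))
        cols.append(block)
        anc.append(auto_q[c])
    if sex_system:
        block = np.concatenate(all_sex, axis=0)
        for p in sex_pos:
            variants.append(Variant(chrom=sex_system, pos_bp=int(p), ref_allele="A",
                                    alt_allele="B", id=f"snp_{sex_system}_{p}"))
        cols.append(block)
        anc.append(sex_q)
    calls = np.concatenate(cols, axis=1)
    anc = np.concatenate(anc)

    n_dropped = 0
    if config.drop_fixed:  # array-like ascertainment: keep only segregating sites
        freqs = calls.mean(axis=0) / 2.0
        keep = (freqs > 0) & (freqs < 1)
        n_dropped = int((~keep).sum())
        calls = calls[:, keep]
        variants = [v for v, k in zip(variants, keep) if k]
        anc = anc[keep]

    matrix = GenotypeMatrix(variants, all_samples, calls)
    truth = SimTruth(populations=pop_truths, ancestral_freqs=anc,
                     sex_system=sex_system, seed=config.seed,
                     n_dropped_fixed=n_dropped)
    return matrix, truth


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------

def default_scenarios(seed: int) -> dict[str, SimConfig]:
    base = dict(n_autosomes=2, snps_per_chrom=150, chrom_length_bp=20_000_000,
                generations=15)
    return {
        "balanced_sex": SimConfig(seed=seed + 1, n_females=15, n_males=15,
                                  sex_chrom="Z", snps_on_sex_chrom=150, **base),
        "skewed_sex_4to1": SimConfig(seed=seed + 2, n_females=24, n_males=6,
                                     sex_chrom="Z", snps_on_sex_chrom=150, **base),
        "ne_small": SimConfig(seed=seed + 3, n_females=10, n_males=10, **base),
        "ne_medium": SimConfig(seed=seed + 4, n_females=30, n_males=30, **base),
        "ne_large": SimConfig(seed=seed + 5, n_females=60, n_males=60, **base),
        "mating_random": SimConfig(seed=seed + 6, n_females=10, n_males=10,
                                   mating="random", **base),
        "mating_half_sib": SimConfig(seed=seed + 7, n_females=10, n_males=10,
                                     mating="half_sib", **base),
        "mating_full_sib": SimConfig(seed=seed + 8, n_females=10, n_males=10,
                                     mating="full_sib", **base),
        "star_15pop": SimConfig(seed=seed + 9, n_populations=15, n_females=4,
                                n_males=4, n_autosomes=2, snps_per_chrom=120,
                                chrom_length_bp=20_000_000, generations=10),
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_fixture_suite(output_dir, scenario_set: dict[str, SimConfig] | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Emit the standard scenarios as VCF + sample sheet + truth TSV + manifest."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenarios = scenario_set if scenario_set is not None else default_scenarios(seed)
    rows = []
    for name, cfg in scenarios.items():
        matrix, truth = simulate(cfg)
        vcf_path = outdir / f"{name}.vcf"
        write_vcf(matrix, vcf_path)
        samples_path = outdir / f"{name}.samples.tsv"
        pd.DataFrame([{"sample_id": s.sample_id, "population": s.population,
                       "sex": s.sex} for s in matrix.samples]
                     ).to_csv(samples_path, sep="\t", index=False)
        truth_path = outdir / f"{name}.truth.tsv"
        truth.to_frame().to_csv(truth_path, sep="\t", index=False)
        for p in (vcf_path, samples_path, truth_path):
            rows.append({"scenario": name, "seed": cfg.seed, "file": p.name,
                         "sha256": _sha256(p)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
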