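import numpy as np
import pytest

from gallipop.genotypes import GenotypeMatrix, SampleRecord, Variant
from gallipop.simulate import SimConfig, simulate


def make_matrix(calls, positions=None, chroms=None, populations=None, sexes=None):
    """Build a GenotypeMatrix from a plain dosage array for tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if chroms is None:
        chroms = ["1"] * m
    variants = [Variant(chrom=str(chroms[j]), pos_bp=int(positions[j]),
                        ref_allele="A", alt_allele="B", id=f"v{j}")
                for j in range(m)]
    populations = populations or ["pop1"] * n
    sexes = sexes or ["unknown"] * n
    samples = [SampleRecord(sample_id=f"s{i}", population=populations[i],
                            sex=sexes[i]) for i in range(n)]
    return GenotypeMatrix(variants, samples, calls)


@pytest.fixture(scope="session")
def two_pop_sim():
    """Two diverged populations with a Z chromosome, modest scale."""
    cfg = SimConfig(seed=42, n_populations=2, n_females=15, n_males=15,
                    generations=25, n_autosomes=3, snps_per_chrom=250,
                    chrom_length_bp=40_000_000, sex_chrom="Z",
                    snps_on_sex_chrom=200, track_pedigree=False)
    return simulate(cfg)


@pytest.fixture(scope="session")
def single_pop_sim():
    cfg = SimConfig(seed=7, n_females=20, n_males=20, generations=20,
                    n_autosomes=3, snps_per_chrom=200,
                    chrom_length_bp=30_000_000, track_pedigree=False)
    return simulate(cfg)
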