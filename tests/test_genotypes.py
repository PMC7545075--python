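"""Core genotype container, I/O round trips, allele frequencies, HWE, QC."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gallipop.genotypes import (MISSING, QCConfig, SampleRecord, Variant,
                                allele_frequency, allele_frequencies, apply_qc,
                                hwe_exact_test, read_plink_text, read_vcf,
                                write_vcf)
from conftest import make_matrix

# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

def test_variant_invariants():
    with pytest.raises(ValueError):
        Variant(chrom="1", pos_bp=0, ref_allele="A", alt_allele="B")
    with pytest.raises(ValueError):
        Variant(chrom="1", pos_bp=5, ref_allele="A", alt_allele="A")
    assert Variant(chrom="Z", pos_bp=5, ref_allele="A", alt_allele="B").is_sex_linked
    assert not Variant(chrom="12", pos_bp=5, ref_allele="A", alt_allele="B").is_sex_linked


def test_matrix_rejects_unsorted_and_bad_calls():
    with pytest.raises(ValueError):
        make_matrix([[0, 1]], positions=[200, 100])
    with pytest.raises(ValueError):
        make_matrix([[0, 3]])
    with pytest.raises(ValueError):  # duplicate sample ids
        vs = [Variant(chrom="1", pos_bp=1, ref_allele="A", alt_allele="B")]
        ss = [SampleRecord("x"), SampleRecord("x")]
        from gallipop.genotypes import GenotypeMatrix
        GenotypeMatrix(vs, ss, np.zeros((2, 1), dtype=np.int8))


# ---------------------------------------------------------------------------
# allele frequency
# ---------------------------------------------------------------------------

def test_allele_frequency_examples():
    m = make_matrix([[0], [1], [2]])
    assert allele_frequency(m, 0) == 0.5
    m2 = make_matrix([[2], [2], [MISSING]])
    assert allele_frequency(m2, 0) == 1.0
    m3 = make_matrix([[MISSING], [MISSING]])
    with pytest.raises(ValueError):
        allele_frequency(m3, 0)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.lists(st.sampled_from([-1, 0, 1, 2]), min_size=4, max_size=4),
                min_size=2, max_size=12))
def test_allele_frequency_matches_loop_oracle(rows):
    calls = np.array(rows, dtype=np.int8)
    freqs = allele_frequencies(calls)
    for j in range(calls.shape[1]):
        col = [c for c in calls[:, j] if c != MISSING]
        if not col:
            assert np.isnan(freqs[j])
        else:
            assert freqs[j] == pytest.approx(sum(col) / (2 * len(col)))


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_aa + n_ab + n_bb
    na = 2 * min(n_aa, n_bb) + n_ab
    def weight(h):
        ra = (na - h) // 2
        rb = (2 * n - na - h) // 2
        return (Fraction(2 ** h) * Fraction(math.factorial(n),
                math.factorial(ra) * math.factorial(h) * math.factorial(rb)))
    hs = [h for h in range(na % 2, na + 1, 2) if (2 * n - na - h) >= 0]
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    obs = weights[n_ab]
    return float(sum(w for w in weights.values() if w <= obs) / total)


def test_hwe_trivial_and_symmetry():
    assert hwe_exact_test(5, 0, 0) == 1.0
    assert hwe_exact_test(57, 14, 50) == pytest.approx(
        hwe_enumeration_oracle(57, 14, 50), abs=1e-12)
    for (a, h, b) in [(10, 3, 2), (4, 7, 9), (0, 5, 20)]:
        assert hwe_exact_test(a, h, b) == pytest.approx(hwe_exact_test(b, h, a),
                                                        abs=1e-15)
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 0, 2)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


@settings(max_examples=120, deadline=None)
@given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
def test_hwe_matches_enumeration_oracle(a, h, b):
    if a + h + b == 0:
        return
    assert hwe_exact_test(a, h, b) == pytest.approx(
        hwe_enumeration_oracle(a, h, b), abs=1e-12)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _toy_qc_matrix():
    """10 variants with known violations under default thresholds, 40 samples."""
    n = 40
    calls = np.zeros((n, 10), dtype=np.int8)
    # v0: healthy (p=0.5, HWE-conforming)
    calls[:, 0] = [0] * 10 + [1] * 20 + [2] * 10
    # v1: MAF 0.0125 < 0.05 -> removed (maf)
    calls[:, 1] = [1] + [0] * 39
    # v2: call rate 0.85 < 0.90 -> removed (call rate)
    calls[:, 2] = [MISSING] * 6 + [0] * 16 + [1] * 12 + [2] * 6
    # v3: all heterozygous (exact p ~1e-11 < 1e-6) -> removed (hwe)
    calls[:, 3] = [1] * n
    # v4: healthy, some missing but rate 0.95
    calls[:, 4] = [MISSING] * 2 + [0] * 10 + [1] * 18 + [2] * 10
    # v5: monomorphic (MAF 0) -> removed (maf)
    calls[:, 5] = 0
    # v6: healthy p=0.25
    calls[:, 6] = [0] * 22 + [1] * 16 + [2] * 2
    # v7: fails maf AND call rate -> reported under maf (precedence)
    calls[:, 7] = [MISSING] * 8 + [0] * 32
    # v8: opposite homozygotes 20/20 (exact p ~1e-12) -> removed (hwe)
    calls[:, 8] = [0] * 20 + [2] * 20
    # v9: healthy
    calls[:, 9] = [0] * 14 + [1] * 20 + [2] * 6
    return make_matrix(calls)


def test_apply_qc_retains_hand_listed_set():
    m = _toy_qc_matrix()
    filtered, report = apply_qc(m)
    assert [v.id for v in filtered.variants] == ["v0", "v4", "v6", "v9"]
    assert report.n_input == 10 and report.n_retained == 4
    assert set(report.removed_maf_ids) == {"v1", "v5", "v7"}
    assert set(report.removed_callrate_ids) == {"v2"}
    assert set(report.removed_hwe_ids) == {"v3", "v8"}
    assert filtered.n_samples == m.n_samples  # samples never removed


def test_qc_idempotent():
    m = _toy_qc_matrix()
    once, _ = apply_qc(m)
    twice, rep2 = apply_qc(once)
    assert [v.id for v in twice.variants] == [v.id for v in once.variants]
    assert rep2.n_retained == rep2.n_input


def test_qc_skips_hwe_on_sex_linked_by_default():
    calls = np.tile([1], (40, 2)).astype(np.int8)  # all-het everywhere
    m = make_matrix(calls, chroms=["1", "Z"], positions=[1000, 1000])
    filtered, report = apply_qc(m)
    kept = [v.chrom for v in filtered.variants]
    assert kept == ["Z"]  # autosomal all-het removed by HWE, Z exempt
    _, rep_override = apply_qc(m, hwe_on_sex_linked=True)
    assert rep_override.n_retained == 0


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

def test_vcf_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    calls = rng.integers(-1, 3, size=(6, 30)).astype(np.int8)
    chroms = ["1"] * 10 + ["2"] * 10 + ["Z"] * 10
    pos = list(range(1000, 11000, 1000)) * 3
    m = make_matrix(calls, chroms=chroms, positions=pos,
                    populations=["A"] * 3 + ["B"] * 3)
    path = tmp_path / "x.vcf"
    write_vcf(m, path)
    back = read_vcf(path)
    assert np.array_equal(back.calls, m.calls)
    assert [v.pos_bp for v in back.variants] == [v.pos_bp for v in m.variants]
    assert back.sample_ids == m.sample_ids


def test_vcf_skips_multiallelic(tmp_path):
    path = tmp_path / "m.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
        "1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t200\tv2\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t300\tv3\tA\tG\t.\tPASS\t.\tGT\t./.\t0/0\t1/1\n")
    with pytest.warns(UserWarning, match="non-biallelic"):
        m = read_vcf(path)
    assert m.n_variants == 2
    assert list(m.calls[:, 0]) == [0, 1, 2]
    assert m.calls[0, 1] == MISSING


def test_plink_round_trip(tmp_path):
    map_path = tmp_path / "x.map"
    ped_path = tmp_path / "x.ped"
    map_path.write_text("1 m1 0 1000\n1 m2 0 2000\n2 m3 0 500\n")
    ped_path.write_text(
        "fam1 i1 0 0 1 -9 A A A G 0 0\n"
        "fam1 i2 0 0 2 -9 A G G G C C\n"
        "fam2 i3 0 0 0 -9 A A A A C C\n")
    m = read_plink_text(ped_path, map_path)
    assert m.sample_ids == ["i1", "i2", "i3"]
    assert [s.population for s in m.samples] == ["fam1", "fam1", "fam2"]
    assert [s.sex for s in m.samples] == ["male", "female", "unknown"]
    # m1: ref A (first seen); dosages 0, 1, 0
    j1 = [v.id for v in m.variants].index("m1")
    assert list(m.calls[:, j1]) == [0, 1, 0]
    # "0 0" -> missing
    j3 = [v.id for v in m.variants].index("m3")
    assert m.calls[0, j3] == MISSING
    # dosage-preserving VCF round trip
    out = tmp_path / "rt.vcf"
    write_vcf(m, out)
    back = read_vcf(out)
    assert np.array_equal(back.calls, m.calls)


def test_plink_errors(tmp_path):
    map_path = tmp_path / "x.map"
    ped_path = tmp_path / "x.ped"
    map_path.write_text("1 m1 0 1000\n")
    ped_path.write_text("f i1 0 0 1 -9 A A G G\n")  # 2 markers worth of alleles
    with pytest.raises(ValueError, match="fields"):
        read_plink_text(ped_path, map_path)
    ped_path.write_text("f i1 0 0 1 -9 A G\nf i2 0 0 1 -9 C C\n")
    with pytest.raises(ValueError, match="2 alleles"):
        read_plink_text(ped_path, map_path)
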