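"""ROH detection vs a brute-force oracle, F_ROH, incidence, and islands."""

import numpy as np
import pytest

from gallipop.genotypes import MISSING
from gallipop.roh import (DEFAULT_L_AUTO_KB, ROHParams, ROHSegment, detect_roh,
                          detect_roh_all, f_roh, l_auto_from_matrix,
                          roh_islands, snp_roh_incidence)
from gallipop.simulate import SimConfig, simulate
from conftest import make_matrix


# ---------------------------------------------------------------------------
# brute-force oracle (independent nested-loop implementation of the contract)
# ---------------------------------------------------------------------------

def brute_force_roh(genos, positions, params: ROHParams):
    """Return (start_bp, end_bp, n_snps) tuples for one chromosome."""
    m = len(genos)
    w = params.window_snps
    passing = []
    n_het = sum(1 for g in genos[:w] if g == 1)
    n_mis = sum(1 for g in genos[:w] if g == MISSING)
    for start in range(m - w + 1):  # rolling window counts
        if start > 0:
            out_g, in_g = genos[start - 1], genos[start + w - 1]
            n_het += int(in_g == 1) - int(out_g == 1)
            n_mis += int(in_g == MISSING) - int(out_g == MISSING)
        passing.append(n_het <= params.max_het_per_window
                       and n_mis <= params.max_missing_per_window)
    candidate = []
    for j in range(m):
        # windows starting in [j-w+1, j] overlap SNP j
        overlapping = passing[max(0, j - w + 1):j + 1]
        if not overlapping:
            candidate.append(False)
        else:
            candidate.append(sum(overlapping) / len(overlapping)
                             >= params.window_hit_threshold)
    segments = []
    run = []
    for j in range(m):
        if not candidate[j]:
            if run:
                segments.append(run)
                run = []
            continue
        if run and (positions[j] - positions[run[-1]]) > params.max_gap_kb * 1000:
            segments.append(run)
            run = []
        run.append(j)
    if run:
        segments.append(run)
    out = []
    for seg in segments:
        length_kb = (positions[seg[-1]] - positions[seg[0]] + 1) / 1000
        if (length_kb >= params.min_length_kb
                and len(seg) >= params.min_snps_per_segment
                and length_kb / len(seg) <= params.min_density_kb_per_snp):
            out.append((positions[seg[0]], positions[seg[-1]], len(seg)))
    return out


def _random_instance(rng, m):
    pos = np.unique(rng.integers(1, 40_000_000, size=2 * m))
    pos = np.sort(rng.choice(pos, size=m, replace=False))
    # blocks of homozygosity interleaved with noisy stretches
    genos = np.empty(m, dtype=np.int8)
    j = 0
    while j < m:
        block = min(m - j, int(rng.integers(10, 200)))
        if rng.random() < 0.5:
            hom = rng.choice([0, 2], size=block)
            noise = rng.random(block)
            hom[noise < 0.02] = 1
            hom[(noise >= 0.02) & (noise < 0.05)] = MISSING
            genos[j:j + block] = hom
        else:
            genos[j:j + block] = rng.choice([0, 1, 2, MISSING], size=block,
                                            p=[0.4, 0.3, 0.25, 0.05])
        j += block
    return genos, pos


@pytest.mark.parametrize("seed", range(8))
def test_detector_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(60, 500))
    genos, pos = _random_instance(rng, m)
    matrix = make_matrix(genos[None, :], positions=pos)
    params = ROHParams()
    got = [(s.start_bp, s.end_bp, s.n_snps) for s in detect_roh(matrix, 0, params)]
    assert got == brute_force_roh(list(genos), list(pos), params)


def test_long_homozygous_run_detected():
    pos = np.arange(1, 201) * 10_000  # 200 SNPs, 10 kb spacing, ~2 Mb
    genos = np.zeros(200, dtype=np.int8)
    m = make_matrix(genos[None, :], positions=pos)
    segs = detect_roh(m, 0)
    assert len(segs) == 1
    assert segs[0].n_snps == 200
    assert segs[0].length_kb == pytest.approx((pos[-1] - pos[0] + 1) / 1000)


def test_short_run_below_min_length_rejected():
    pos = np.arange(1, 31) * 3_000  # 30 SNPs over 90 kb
    genos = np.zeros(30, dtype=np.int8)
    m = make_matrix(genos[None, :], positions=pos)
    assert detect_roh(m, 0) == []


def test_segments_respect_all_constraints(two_pop_sim):
    matrix, _ = two_pop_sim
    params = ROHParams()
    for sid, segs in detect_roh_all(matrix, params).items():
        by_chrom = {}
        for s in segs:
            assert s.length_kb >= params.min_length_kb
            assert s.n_snps >= params.min_snps_per_segment
            assert s.length_kb / s.n_snps <= params.min_density_kb_per_snp
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom_segs in by_chrom.values():
            chrom_segs.sort(key=lambda s: s.start_bp)
            for a, b in zip(chrom_segs, chrom_segs[1:]):
                assert b.start_bp > a.end_bp  # never overlapping


def test_f_roh_arithmetic():
    segs = [ROHSegment(sample_id="s", chrom="1", start_bp=1, end_bp=95_209_000,
                       n_snps=1000)]
    assert f_roh(segs) == pytest.approx(95_209 / 952_090)
    assert f_roh([]) == 0.0
    full = [ROHSegment(sample_id="s", chrom="1", start_bp=1,
                       end_bp=952_090_000, n_snps=1000)]
    assert f_roh(full) == pytest.approx(1.0)


def test_f_roh_rejects_overlap():
    segs = [ROHSegment(sample_id="s", chrom="1", start_bp=100, end_bp=2000, n_snps=30),
            ROHSegment(sample_id="s", chrom="1", start_bp=1500, end_bp=3000, n_snps=30)]
    with pytest.raises(ValueError, match="overlap"):
        f_roh(segs)


def test_incidence_against_stabbing_oracle():
    rng = np.random.default_rng(6)
    m = 150
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=m, replace=False))
    matrix = make_matrix(np.zeros((10, m), dtype=np.int8), positions=pos)
    segs = {}
    for i in range(10):
        sid = f"s{i}"
        segs[sid] = []
        lo = int(rng.integers(0, m - 20))
        hi = lo + int(rng.integers(5, 20))
        if rng.random() < 0.8:
            segs[sid].append(ROHSegment(sample_id=sid, chrom="1",
                                        start_bp=int(pos[lo]), end_bp=int(pos[hi]),
                                        n_snps=hi - lo + 1))
    inc = snp_roh_incidence(segs, matrix, "pop1")
    for j in rng.choice(m, 30, replace=False):
        covered = sum(1 for sid in segs for s in segs[sid]
                      if s.start_bp <= pos[j] <= s.end_bp)
        assert inc["incidence"].iloc[j] == pytest.approx(covered / 10)
    # one of ten individuals covering a SNP -> 0.1
    only = {f"s{i}": [] for i in range(10)}
    only["s0"] = [ROHSegment(sample_id="s0", chrom="1", start_bp=int(pos[0]),
                             end_bp=int(pos[5]), n_snps=6)]
    inc2 = snp_roh_incidence(only, matrix, "pop1")
    assert inc2["incidence"].iloc[0] == 0.1
    # no ROH at all -> zeros
    none = {f"s{i}": [] for i in range(10)}
    assert (snp_roh_incidence(none, matrix, "pop1")["incidence"] == 0).all()


def test_islands_clear_separation():
    import pandas as pd
    inc = pd.DataFrame({"chrom": ["1"] * 1000,
                        "pos_bp": np.arange(1, 1001) * 1000,
                        "incidence": [0.1] * 1000})
    inc.loc[500:509, "incidence"] = 0.9
    islands = roh_islands(inc)
    assert len(islands) == 1
    isl = islands[0]
    assert isl.start_bp == 501 * 1000 and isl.end_bp == 510 * 1000
    assert isl.n_snps == 10 and isl.peak_incidence == 0.9


def test_islands_tie_case_one_per_chrom():
    import pandas as pd
    inc = pd.DataFrame({"chrom": ["1"] * 60 + ["2"] * 60,
                        "pos_bp": list(np.arange(1, 61) * 1000) * 2,
                        "incidence": [0.4] * 120})
    islands = roh_islands(inc)
    assert [i.chrom for i in islands] == ["1", "2"]
    assert (roh_islands(inc.assign(incidence=0.0))) == []


def test_islands_match_quantile_then_merge_oracle():
    import pandas as pd
    rng = np.random.default_rng(12)
    vals = rng.choice([0, 0.1, 0.2, 0.5, 0.9], size=400,
                      p=[0.3, 0.3, 0.2, 0.15, 0.05])
    inc = pd.DataFrame({"chrom": ["1"] * 200 + ["2"] * 200,
                        "pos_bp": list(np.arange(1, 201) * 997) * 2,
                        "incidence": vals})
    thr = np.quantile(vals, 0.99)
    sel = (vals >= thr) & (vals > 0)
    expected = []
    j = 0
    while j < 400:
        if sel[j]:
            k = j
            while k + 1 < 400 and sel[k + 1] and (k + 1) % 200 != 0:
                k += 1
            expected.append((j, k))
            j = k + 1
        else:
            j += 1
    got = roh_islands(inc)
    assert len(got) == len(expected)
    for isl, (j, k) in zip(got, expected):
        assert isl.n_snps == k - j + 1


def test_f_roh_orders_with_mating_scheme():
    """Pedigree inbreeding drives ROH: full-sib > half-sib > random mating."""
    means = {}
    for scheme, seed in (("random", 21), ("half_sib", 22), ("full_sib", 23)):
        vals = []
        for rep in range(3):
            cfg = SimConfig(seed=seed + 10 * rep, n_females=8, n_males=8,
                            generations=12, n_autosomes=2, snps_per_chrom=600,
                            chrom_length_bp=12_000_000, mating=scheme,
                            drop_fixed=False, track_pedigree=False)
            matrix, _ = simulate(cfg)
            la = l_auto_from_matrix(matrix)
            segs = detect_roh_all(matrix)
            vals += [f_roh(s, la) for s in segs.values()]
        means[scheme] = np.mean(vals)
    assert means["full_sib"] > means["half_sib"] > means["random"]
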