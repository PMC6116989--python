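import numpy as np
import pandas as pd
import pytest

from polledgwas.roh import (
    RohIsland,
    RohParams,
    call_islands,
    detect_roh,
    intersect_regions,
    snp_incidence,
    window_support,
)
from polledgwas.wssgwas import CandidateRegion
from _oracles import random_roh_fixture, roh_enumerate, roh_window_support
from conftest import make_geno


def geno_one_animal(g, bp):
    return make_geno(np.asarray(g, dtype=np.int8)[None, :], bp=bp)


class TestDetect:
    def test_short_span_rejected(self):
        # 120 homozygous SNPs over 0.8 Mb: fails the 1 Mb minimum
        bp = np.linspace(1, 800_000, 120).astype(np.int64)
        segs = detect_roh(geno_one_animal(np.zeros(120), bp))
        assert segs == []

    def test_clean_run_detected(self):
        # 150 homozygous SNPs at uniform 10 kb spacing
        bp = np.arange(1, 151) * 10_000
        segs = detect_roh(geno_one_animal(np.full(150, 2), bp))
        assert len(segs) == 1
        s = segs[0]
        assert (s.n_snps, s.start_bp, s.end_bp, s.n_het) == (150, 10_000, 1_500_000, 0)

    def test_two_hets_match_oracle(self):
        g = np.full(150, 2, dtype=np.int8)
        g[40] = 1
        g[100] = 1
        bp = np.arange(1, 151) * 10_000
        params = RohParams()
        got = {(s.start_bp, s.end_bp) for s in detect_roh(geno_one_animal(g, bp), params)}
        want = {(int(bp[i]), int(bp[j])) for i, j in roh_enumerate(g, bp, params)}
        assert got == want

    def test_gap_splits_run(self):
        bp = np.arange(1, 301) * 10_000
        bp[150:] += 600_000  # 0.61 Mb gap in the middle
        segs = detect_roh(geno_one_animal(np.full(300, 0), bp), RohParams())
        assert len(segs) == 2
        assert all(s.n_snps == 150 for s in segs)

    def test_window_support_matches_direct_loops(self):
        rng = np.random.default_rng(30)
        g, _ = random_roh_fixture(rng, 200)
        p = RohParams()
        np.testing.assert_array_equal(
            window_support(g, p),
            roh_window_support(g, p.window_snps, p.het_in_window,
                               p.missing_in_window, p.overlap_threshold),
        )

    def test_detector_equals_exhaustive_enumerator(self):
        params = RohParams()
        rng = np.random.default_rng(31)
        total = 0
        for _ in range(12):
            g, bp = random_roh_fixture(rng, int(rng.integers(120, 301)))
            got = {(s.start_bp, s.end_bp, s.n_snps)
                   for s in detect_roh(geno_one_animal(g, bp), params)}
            want = {(int(bp[i]), int(bp[j]), j - i + 1) for i, j in roh_enumerate(g, bp, params)}
            assert got == want
            total += len(want)
        assert total > 0  # the fixtures do exercise the detector

    def test_emitted_segments_satisfy_all_constraints(self, default_dataset):
        params = RohParams()
        geno = default_dataset.genotypes
        segs = detect_roh(geno, params)
        assert segs, "default population should contain ROH"
        bp = geno.snp_map.bp.values
        chrom = geno.snp_map.chrom.values
        rows = {int(a): i for i, a in enumerate(geno.animal_ids)}
        for s in segs:
            idx = np.flatnonzero((chrom == s.chrom) & (bp >= s.start_bp) & (bp <= s.end_bp))
            g = geno.M[rows[s.animal_id], idx]
            assert s.n_snps == len(idx) >= params.min_snps
            assert s.length_bp >= params.min_length_bp
            assert np.sum(g == 1) == s.n_het <= params.het_in_roh
            assert np.max(np.diff(bp[idx])) <= params.max_gap_bp
            assert s.length_bp <= s.n_snps * params.max_bp_per_snp

    def test_relaxing_thresholds_never_drops_segments(self):
        rng = np.random.default_rng(32)
        strict = RohParams()
        relaxed_snps = RohParams(min_snps=50)
        relaxed_len = RohParams(min_length_bp=500_000)
        for _ in range(8):
            g, bp = random_roh_fixture(rng, 250)
            geno = geno_one_animal(g, bp)
            base = {(s.start_bp, s.end_bp) for s in detect_roh(geno, strict)}
            for relaxed in (relaxed_snps, relaxed_len):
                got = {(s.start_bp, s.end_bp) for s in detect_roh(geno, relaxed)}
                for i, j in base:
                    assert any(i2 <= i and j2 >= j for (i2, j2) in got)


class TestIncidence:
    def test_no_segments_all_zero(self):
        m = make_geno(np.zeros((3, 10), dtype=np.int8)).snp_map
        np.testing.assert_array_equal(snp_incidence([], m, 10), np.zeros(10))

    def test_single_covering_animal(self):
        geno = make_geno(np.zeros((1, 10), dtype=np.int8))
        from polledgwas.roh import RohSegment

        s = RohSegment(animal_id=1, chrom="1", start_bp=30_000, end_bp=60_000, n_snps=4, n_het=0)
        inc = snp_incidence([s], geno.snp_map, 10)
        np.testing.assert_allclose(inc[2:6], 0.1)
        assert inc[0] == inc[6] == 0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(33)
        from polledgwas.roh import RohSegment

        snp_map = make_geno(np.zeros((1, 60), dtype=np.int8)).snp_map
        bp = snp_map.bp.values
        segs = []
        for _ in range(25):
            a = int(rng.integers(1, 8))
            i, j = sorted(rng.integers(0, 60, size=2))
            segs.append(RohSegment(animal_id=a, chrom="1", start_bp=int(bp[i]),
                                   end_bp=int(bp[j]), n_snps=j - i + 1, n_het=0))
        inc = snp_incidence(segs, snp_map, 8)
        direct = np.zeros(60)
        for s_idx in range(60):
            animals = {s.animal_id for s in segs if s.start_bp <= bp[s_idx] <= s.end_bp}
            direct[s_idx] = len(animals) / 8
        np.testing.assert_allclose(inc, direct)


class TestIslands:
    def make_map(self, n):
        return make_geno(np.zeros((1, n), dtype=np.int8)).snp_map

    def test_island_called_for_150_elevated_snps(self):
        inc = np.full(1000, 0.05)
        inc[300:450] = 0.80
        islands = call_islands(inc, self.make_map(1000))
        assert len(islands) == 1
        isl = islands[0]
        np.testing.assert_array_equal(isl.snp_indices, np.arange(300, 450))

    def test_99_consecutive_outliers_are_not_an_island(self):
        inc = np.full(1000, 0.05)
        inc[300:399] = 0.80
        assert call_islands(inc, self.make_map(1000)) == []

    def test_constant_incidence_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning):
            assert call_islands(np.zeros(500), self.make_map(500)) == []

    def test_fence_uses_quartiles(self):
        # background spread makes the fence Q3 + 1.5 IQR; values below it
        # are not outliers even if above the median
        rng = np.random.default_rng(34)
        inc = rng.uniform(0.0, 0.2, size=2000)
        inc[500:700] = 0.21  # above all background but below the fence?
        q1, q3 = np.percentile(inc, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        islands = call_islands(inc, self.make_map(2000))
        if 0.21 > fence:
            assert len(islands) == 1
        else:
            assert islands == []


class TestConsensus:
    def test_reported_intersection(self):
        gwas = [CandidateRegion(chrom="1", start_bp=878_631, end_bp=3_987_104,
                                total_var_share_pct=65.54)]
        island = RohIsland(chrom="1", start_bp=269_100, end_bp=2_739_000,
                           snp_indices=np.array([]), incidences=np.array([]))
        (c,) = intersect_regions(gwas, [island])
        assert (c.start_bp, c.end_bp) == (878_631, 2_739_000)
        assert c.length_bp == 1_860_369  # ~1.86 Mb
        assert c.source == "consensus"

    def test_disjoint_is_empty(self):
        gwas = [CandidateRegion(chrom="1", start_bp=100, end_bp=200, total_var_share_pct=2.0)]
        island = RohIsland(chrom="1", start_bp=300, end_bp=400,
                           snp_indices=np.array([]), incidences=np.array([]))
        assert intersect_regions(gwas, [island]) == []

    def test_identical_intervals_idempotent(self):
        gwas = [CandidateRegion(chrom="2", start_bp=10, end_bp=99, total_var_share_pct=5.0)]
        island = RohIsland(chrom="2", start_bp=10, end_bp=99,
                           snp_indices=np.array([]), incidences=np.array([]))
        (c,) = intersect_regions(gwas, [island])
        assert (c.start_bp, c.end_bp) == (10, 99)

    def test_chromosome_mismatch_ignored(self):
        gwas = [CandidateRegion(chrom="1", start_bp=10, end_bp=99, total_var_share_pct=5.0)]
        island = RohIsland(chrom="2", start_bp=10, end_bp=99,
                           snp_indices=np.array([]), incidences=np.array([]))
        assert intersect_regions(gwas, [island]) == []
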