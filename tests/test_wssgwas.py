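import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polledgwas.simdata import SimConfig, simulate_dataset
from polledgwas.gqc import qc_filter
from polledgwas.tgibbs import GibbsConfig
from polledgwas.wssgwas import (
    WindowResult,
    WssgwasConfig,
    backsolve_snp_effects,
    normalize_weights,
    run_iterations,
    select_regions,
    sliding_windows,
    snp_variances,
    tiling_windows,
    window_variances,
)
from _oracles import weighted_min_norm_backsolve, window_share_direct


def make_map(bp, chrom=None):
    chrom = ["1"] * len(bp) if chrom is None else [str(c) for c in chrom]
    return pd.DataFrame({"snp": [f"s{i}" for i in range(len(bp))], "chrom": chrom,
                         "bp": np.asarray(bp, dtype=np.int64)})


class TestBacksolve:
    def test_scalar_case(self):
        Z = np.array([[0.8]])
        u = backsolve_snp_effects(np.array([0.4]), Z)
        assert u[0] == pytest.approx(0.4 / 0.8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_projection_identity(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 6, 20
        Z = rng.normal(size=(n, m))
        a = rng.normal(size=n)
        d = rng.uniform(0.2, 3.0, size=m)
        u = backsolve_snp_effects(a, Z, D=d)
        np.testing.assert_allclose(Z @ u, a, atol=1e-8)

    def test_matches_min_norm_oracle(self):
        rng = np.random.default_rng(12)
        Z = rng.normal(size=(3, 5))
        a = rng.normal(size=3)
        # unweighted: the Moore-Penrose least-norm solution
        np.testing.assert_allclose(
            backsolve_snp_effects(a, Z), np.linalg.pinv(Z) @ a, atol=1e-10
        )
        # weighted: KKT solution of min u' D^-1 u subject to Z u = a
        d = rng.uniform(0.3, 2.0, size=5)
        np.testing.assert_allclose(
            backsolve_snp_effects(a, Z, D=d), weighted_min_norm_backsolve(a, Z, d), atol=1e-10
        )

    def test_both_forms_of_the_backsolve_agree(self):
        rng = np.random.default_rng(13)
        Z = rng.normal(size=(4, 9))
        p = rng.uniform(0.1, 0.9, size=9)
        d = rng.uniform(0.5, 1.5, size=9)
        a = rng.normal(size=4)
        lam = 1.0 / np.sum(2 * p * (1 - p))
        G_star = (Z * d) @ Z.T * lam
        u1 = backsolve_snp_effects(a, Z, D=d)
        u2 = backsolve_snp_effects(a, Z, D=d, G_star_inv=np.linalg.inv(G_star), lam=lam)
        np.testing.assert_allclose(u1, u2, atol=1e-8)


class TestSnpVariances:
    def test_formula(self):
        assert snp_variances(np.array([0.1]), np.array([0.5]))[0] == pytest.approx(0.005)
        assert snp_variances(np.array([0.0]), np.array([0.3]))[0] == 0.0

    def test_frequency_ratio(self):
        u = np.array([0.2, 0.2])
        v = snp_variances(u, np.array([0.1, 0.5]))
        assert v[0] / v[1] == pytest.approx(0.18 / 0.5)


class TestWeights:
    def test_uniform_raw_gives_identity(self):
        p = np.array([0.2, 0.3, 0.4])
        np.testing.assert_allclose(normalize_weights(np.full(3, 0.7), p), np.ones(3))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 50))
        p = rng.uniform(0.05, 0.95, size=m)
        raw = rng.exponential(size=m)
        d = normalize_weights(raw, p)
        het = 2 * p * (1 - p)
        assert np.sum(d * het) == pytest.approx(np.sum(het), abs=1e-12)

    def test_single_snp_carries_everything(self):
        p = np.array([0.2, 0.4, 0.25])
        raw = np.array([0.0, 3.0, 0.0])
        d = normalize_weights(raw, p)
        het = 2 * p * (1 - p)
        assert d[0] == d[2] == 0.0
        assert d[1] == pytest.approx(het.sum() / het[1])

    def test_zero_raw_falls_back_to_identity(self):
        with pytest.warns(UserWarning):
            d = normalize_weights(np.zeros(4), np.full(4, 0.3))
        np.testing.assert_array_equal(d, np.ones(4))

    def test_negative_raw_rejected(self):
        with pytest.raises(ValueError):
            normalize_weights(np.array([-0.1, 0.2]), np.array([0.5, 0.5]))


class TestWindows:
    def test_sliding_span_rule(self):
        bp = [1, 400_000, 999_999, 1_000_001, 1_500_000]
        w = sliding_windows(make_map(bp))
        # window starting at SNP 0 may include bp 999,999 (span == 1 Mb
        # inclusive) but not 1,000,001
        assert list(w[0]) == [0, 1, 2]
        assert all(bp[idx[-1]] - bp[idx[0]] + 1 <= 1_000_000 for idx in w)
        assert len(w) == 5  # one window per starting SNP

    def test_sliding_windows_respect_chromosomes(self):
        m = make_map([1, 100, 1, 100], chrom=[1, 1, 2, 2])
        w = sliding_windows(m)
        assert [list(x) for x in w] == [[0, 1], [1], [2, 3], [3]]

    def test_tiling_partitions(self):
        m = make_map([1, 500_000, 1_000_000, 1_000_001, 2_500_000])
        w = tiling_windows(m)
        assert [list(x) for x in w] == [[0, 1, 2], [3], [4]]

    def test_zero_effects_zero_shares(self):
        rng = np.random.default_rng(14)
        Z = rng.normal(size=(8, 5))
        res = window_variances(np.zeros(5), Z, make_map([1, 2, 3, 4, 5]), 1.0)
        assert all(w.var_share_pct == 0 for w in res)

    def test_single_window_collapse(self):
        rng = np.random.default_rng(15)
        Z = rng.normal(size=(10, 4))
        u = rng.normal(size=4)
        res = window_variances(u, Z, make_map([1, 10, 20, 30]), 0.5)
        expect = 100 * np.var(Z @ u) / 0.5
        assert res[0].var_share_pct == pytest.approx(expect)

    def test_shares_match_direct_recomputation(self):
        rng = np.random.default_rng(16)
        m = 30
        bp = np.sort(rng.integers(1, 3_000_000, size=m))
        snp_map = make_map(bp)
        Z = rng.normal(size=(12, m))
        u = rng.normal(size=m)
        res = window_variances(u, Z, snp_map, 0.99, mode="tiling")
        for w, idx in zip(res, tiling_windows(snp_map)):
            assert w.var_share_pct == pytest.approx(
                window_share_direct(u, Z, idx, 0.99), rel=1e-9
            )

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            window_variances(np.array([]), np.empty((2, 0)), make_map([]), 1.0)


def wr(chrom, start, end, share, first):
    return WindowResult(chrom=str(chrom), start_bp=start, end_bp=end, snp_count=10,
                        var_share_pct=share, snp_ids=[], first_snp_index=first)


class TestSelectRegions:
    def test_reported_three_window_example(self):
        windows = [
            wr(1, 878_631, 1_873_922, 47.18, 0),
            wr(1, 1_983_902, 2_983_314, 14.66, 10),
            wr(1, 2_987_912, 3_987_104, 3.70, 20),
            wr(1, 5_000_000, 5_900_000, 0.50, 30),
        ]
        regions = select_regions(windows, 1.0)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_bp, r.end_bp) == (878_631, 3_987_104)
        assert r.total_var_share_pct == pytest.approx(65.54)

    def test_all_below_threshold(self):
        assert select_regions([wr(1, 1, 10, 0.5, 0), wr(1, 11, 20, 0.5, 1)]) == []

    def test_exactly_one_percent_excluded(self):
        assert select_regions([wr(1, 1, 10, 1.0, 0)]) == []

    def test_overlapping_sliding_windows_not_double_counted(self):
        windows = [
            wr(1, 100, 1_000, 5.0, 0),
            wr(1, 500, 1_500, 4.0, 1),  # overlaps the first; excluded from total
            wr(1, 1_200, 2_000, 2.0, 2),  # disjoint from the first; counted
        ]
        (r,) = select_regions(windows, 1.0)
        assert (r.start_bp, r.end_bp) == (100, 2_000)
        assert r.total_var_share_pct == pytest.approx(7.0)


@pytest.fixture(scope="module")
def mini():
    cfg = SimConfig(
        n_founders=30, n_generations=2, n_chromosomes=2, chrom_length_bp=3_000_000,
        n_snps_per_chrom=80, causal_pos_bp=1_000_000, causal_block_bp=1_200_000,
        genotyped_fraction=0.8, seed=21,
    )
    ds = simulate_dataset(cfg)
    geno, _ = qc_filter(ds.genotypes)
    return ds, geno


class TestIterations:
    def gcfg(self, seed=5):
        return GibbsConfig(n_cycles=400, burn_in=100, thin=2, seed=seed)

    def test_zero_loops_is_unweighted_gwas(self, mini):
        ds, geno = mini
        res = run_iterations(ds.pedigree, geno, ds.phenotypes,
                             WssgwasConfig(n_loops=0, gibbs=self.gcfg()))
        assert len(res) == 1
        np.testing.assert_array_equal(res[0].weights, np.ones(geno.n_snps))

    def test_default_one_loop_gives_two_effect_sets(self, mini):
        ds, geno = mini
        res = run_iterations(ds.pedigree, geno, ds.phenotypes,
                             WssgwasConfig(gibbs=self.gcfg()))
        assert len(res) == 2
        assert [e.iteration for e in res] == [0, 1]

    def test_end_to_end_reproducible(self, mini):
        ds, geno = mini
        cfg = WssgwasConfig(gibbs=self.gcfg(seed=9))
        r1 = run_iterations(ds.pedigree, geno, ds.phenotypes, cfg)
        r2 = run_iterations(ds.pedigree, geno, ds.phenotypes, cfg)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.u_hat, b.u_hat)

    def test_no_genotyped_animals_rejected(self, mini):
        ds, _ = mini
        empty = ds.genotypes.subset(animals=np.zeros(ds.genotypes.n_animals, dtype=bool))
        with pytest.raises(ValueError, match="genotyped"):
            run_iterations(ds.pedigree, empty, ds.phenotypes, WssgwasConfig(gibbs=self.gcfg()))
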