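"""Pairwise r^2 against a naive oracle, expanding binning, and decay-distance
threshold reading; haplotype-block parameter recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from germpop import (MISSING, bin_ld, decay_distance, expanding_scheme,
                     pairwise_r2, simulate_ld_haplotypes)
from germpop.ld_decay import LDBinning

from conftest import make_matrix


def naive_r2(matrix, chrom, max_dist):
    """O(L^2) double loop with per-pair complete-sample Pearson r^2."""
    out = []
    loci = [(j, l) for j, l in enumerate(matrix.loci) if l.chrom == chrom]
    for a in range(len(loci)):
        for b in range(a + 1, len(loci)):
            ja, la = loci[a]
            jb, lb = loci[b]
            dist = abs(lb.pos - la.pos)
            if dist > max_dist:
                continue
            x, y = [], []
            for i in range(matrix.n_samples):
                ca, cb = matrix.calls[i, ja], matrix.calls[i, jb]
                if ca != MISSING and cb != MISSING:
                    x.append(float(ca))
                    y.append(float(cb))
            if len(x) < 2 or len(set(x)) < 2 or len(set(y)) < 2:
                continue
            r = np.corrcoef(x, y)[0, 1]
            out.append((la.pos, lb.pos, dist, r * r))
    return out


class TestPairwiseR2:
    def test_identical_vectors(self):
        m = make_matrix([[0, 0], [1, 1], [2, 2], [2, 2]])
        pairs = pairwise_r2(m, "A01", max_dist=1000)
        assert len(pairs) == 1
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_hand_value(self):
        # x=(0,1,2,2), y=(0,1,2,0): r^2 = 25/121
        m = make_matrix([[0, 0], [1, 1], [2, 2], [2, 0]])
        pairs = pairwise_r2(m, "A01", max_dist=1000)
        assert pairs["r2"].iloc[0] == pytest.approx(25 / 121, abs=1e-9)

    def test_monomorphic_pair_skipped(self):
        m = make_matrix([[0, 1], [0, 2], [0, 1]])
        pairs = pairwise_r2(m, "A01", max_dist=1000)
        assert pairs.empty

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(-1, 3, size=(25, 50)).astype(np.int8)
        positions = sorted(rng.choice(100_000, size=50, replace=False) + 1)
        m = make_matrix(calls, positions=[int(p) for p in positions])
        got = pairwise_r2(m, "A01", max_dist=40_000)
        expect = naive_r2(m, "A01", 40_000)
        assert len(got) == len(expect)
        got_map = {(r.pos_i, r.pos_j): r.r2 for r in got.itertuples()}
        for pi, pj, _dist, r2 in expect:
            assert got_map[(pi, pj)] == pytest.approx(r2, abs=1e-9)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(20, 10)).astype(np.int8)
        p1 = pairwise_r2(make_matrix(calls), "A01", 10_000)
        p2 = pairwise_r2(make_matrix(2 - calls), "A01", 10_000)
        np.testing.assert_allclose(p1["r2"], p2["r2"], atol=1e-12)

    def test_single_locus_chromosome(self):
        m = make_matrix([[0], [1]])
        assert pairwise_r2(m, "A01", 1000).empty
        assert pairwise_r2(m, "Z99", 1000).empty

    def test_max_dist_respected(self):
        m = make_matrix([[0, 0, 0], [1, 1, 1], [2, 2, 0], [0, 2, 1]],
                        positions=[100, 200, 100_000])
        pairs = pairwise_r2(m, "A01", max_dist=500)
        assert set(pairs["distance_bp"]) == {100}


class TestBinning:
    def test_single_bin_mean(self):
        pairs = pd.DataFrame({"distance_bp": [10, 20, 30],
                              "r2": [0.2, 0.4, 0.9]})
        b = bin_ld(pairs, scheme=np.array([0, 100]))
        assert b.mean_r2[0] == pytest.approx(0.5)
        assert b.counts[0] == 3

    def test_against_naive_sums(self):
        rng = np.random.default_rng(1)
        pairs = pd.DataFrame({
            "distance_bp": rng.integers(1, 5_000_000, size=500),
            "r2": rng.random(500),
        })
        scheme = expanding_scheme()
        b = bin_ld(pairs, scheme)
        for k in range(len(scheme) - 1):
            lo, hi = scheme[k], scheme[k + 1]
            sel = pairs[(pairs.distance_bp > lo) & (pairs.distance_bp <= hi)]
            assert b.counts[k] == len(sel)
            if len(sel):
                assert b.mean_r2[k] == pytest.approx(sel.r2.mean())
            else:
                assert np.isnan(b.mean_r2[k])
        assert b.counts.sum() == 500  # each pair in exactly one bin

    def test_pair_beyond_last_edge_fatal(self):
        pairs = pd.DataFrame({"distance_bp": [200], "r2": [0.5]})
        with pytest.raises(ValueError, match="exceeds"):
            bin_ld(pairs, scheme=np.array([0, 100]))

    def test_default_scheme_structure(self):
        edges = expanding_scheme(5_000_000)
        widths = np.diff(edges)
        assert edges[0] == 0 and edges[-1] == 5_000_000
        assert (widths > 0).all()
        assert widths[0] == 10_000 and widths[-1] == 250_000
        # widths only ever expand
        assert (np.diff(widths) >= 0).all()


class TestDecayDistance:
    def _binning(self, means, mids):
        means = np.asarray(means, float)
        mids = np.asarray(mids, float)
        edges = np.concatenate([[0], mids + (mids[0])])
        return LDBinning(edges=edges, mean_r2=means,
                         counts=np.ones(len(means), dtype=np.int64),
                         midpoints=mids)

    def test_linear_interpolation(self):
        b = self._binning([0.5, 0.3, 0.1], [5_000, 15_000, 25_000])
        dist, status = decay_distance(b, 0.2)
        assert status == "ok"
        assert dist == pytest.approx(20_000)

    def test_not_reached(self):
        b = self._binning([0.9, 0.9, 0.9], [5, 15, 25])
        dist, status = decay_distance(b, 0.2)
        assert dist is None and status == "not_reached"

    def test_below_at_origin(self):
        b = self._binning([0.1, 0.05], [5, 15])
        dist, status = decay_distance(b, 0.2)
        assert dist == 0.0 and status == "below_at_origin"

    def test_empty_bins_skipped(self):
        b = LDBinning(edges=np.array([0, 10, 20, 30, 40]),
                      mean_r2=np.array([0.5, np.nan, 0.1, np.nan]),
                      counts=np.array([3, 0, 3, 0]),
                      midpoints=np.array([5.0, 15.0, 25.0, 35.0]))
        dist, status = decay_distance(b, 0.2)
        assert status == "ok"
        # interpolates between the two non-empty midpoints 5 and 25
        assert dist == pytest.approx(5 + (0.3 / 0.4) * 20)


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.tuples(st.integers(1, 4_999_999),
                          st.floats(0, 1, allow_nan=False)),
                min_size=1, max_size=60))
def test_every_pair_lands_in_exactly_one_bin(pairs_raw):
    pairs = pd.DataFrame({"distance_bp": [d for d, _ in pairs_raw],
                          "r2": [r for _, r in pairs_raw]})
    b = bin_ld(pairs, expanding_scheme(5_000_000))
    assert b.counts.sum() == len(pairs)
    total = np.nansum(b.mean_r2 * np.where(b.counts > 0, b.counts, 0))
    assert total == pytest.approx(pairs["r2"].sum(), abs=1e-9)


class TestHaplotypeBlocks:
    def test_perfect_copying_r2_one(self):
        m, _ = simulate_ld_haplotypes(n_samples=60, n_loci=20,
                                      block_len=1_000_000, rho_within=1.0,
                                      chrom_len=1_000_000, seed=2)
        pairs = pairwise_r2(m, "A01", 1_000_000)
        assert not pairs.empty
        assert (pairs["r2"] > 0.999).all()

    def test_founder_correlation_recovers_rho(self):
        rho = 0.8
        m, truth = simulate_ld_haplotypes(n_samples=500, n_loci=40,
                                          block_len=200_000, rho_within=rho,
                                          chrom_len=400_000, seed=3,
                                          inbreeding=0.0)
        # phased-truth oracle: correlation of haplotype alleles with the
        # founder indicator of their block
        h = truth.haplotypes.astype(float)
        z = truth.founder_indicators.astype(float)
        corrs = [np.corrcoef(h[:, j], z[:, j])[0, 1] for j in range(40)]
        assert np.mean(corrs) == pytest.approx(rho, abs=0.03)

    def test_cross_block_independence_baseline(self):
        # haplotype-level r^2 across blocks nulls at ~1/(2n-1) with 2n
        # independent haplotypes; genotype-level r^2 at ~1/(n-1): both -> 0
        n = 200
        hap_r2s, geno_r2s = [], []
        for seed in range(5):
            m, truth = simulate_ld_haplotypes(n_samples=n, n_loci=30,
                                              block_len=50_000, rho_within=0.9,
                                              chrom_len=600_000, seed=seed,
                                              inbreeding=0.0)
            h = truth.haplotypes.astype(float)
            blocks = truth.block_ids
            for i in range(30):
                for j in range(i + 1, 30):
                    if blocks[i] != blocks[j]:
                        hap_r2s.append(np.corrcoef(h[:, i], h[:, j])[0, 1] ** 2)
            pairs = pairwise_r2(m, "A01", 600_000)
            pos_blocks = dict(zip([l.pos for l in m.loci], blocks))
            cross = pairs[[pos_blocks[r.pos_i] != pos_blocks[r.pos_j]
                           for r in pairs.itertuples()]]
            geno_r2s.append(cross["r2"].mean())
        assert np.mean(hap_r2s) == pytest.approx(1 / (2 * n - 1), rel=0.35)
        assert np.mean(geno_r2s) == pytest.approx(1 / (n - 1), rel=0.35)

    def test_genotype_r2_matches_haplotype_frequency_r2(self):
        # random mating: genotype-correlation r^2 vs D^2/(p(1-p)q(1-q))
        m, truth = simulate_ld_haplotypes(n_samples=400, n_loci=12,
                                          block_len=100_000, rho_within=0.9,
                                          chrom_len=100_000, seed=8,
                                          inbreeding=0.0)
        h = truth.haplotypes.astype(float)
        pairs = pairwise_r2(m, "A01", 100_000)
        pos_idx = {l.pos: j for j, l in enumerate(m.loci)}
        for row in pairs.itertuples():
            i, j = pos_idx[row.pos_i], pos_idx[row.pos_j]
            pa, pb = h[:, i].mean(), h[:, j].mean()
            d_ab = (h[:, i] * h[:, j]).mean() - pa * pb
            hap_r2 = d_ab ** 2 / (pa * (1 - pa) * pb * (1 - pb))
            assert row.r2 == pytest.approx(hap_r2, abs=0.05)

    def test_within_exceeds_cross_every_seed(self):
        for seed in range(5):
            m, truth = simulate_ld_haplotypes(n_samples=120, n_loci=60,
                                              block_len=100_000,
                                              rho_within=0.95,
                                              chrom_len=600_000, seed=seed)
            pairs = pairwise_r2(m, "A01", 600_000)
            blocks = dict(zip([l.pos for l in m.loci], truth.block_ids))
            same = np.array([blocks[r.pos_i] == blocks[r.pos_j]
                             for r in pairs.itertuples()])
            assert pairs["r2"][same].mean() > pairs["r2"][~same].mean()
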