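"""Two-caller deletion consensus, sweep-line region combination vs a
per-base oracle, filtering, and annotation summaries."""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pytest

from germpop import (GeneModel, IntervalCall, PopulationMap, SimConfig,
                     Transcript, annotate_svs, build_gene_index,
                     combine_regions, consensus_deletions, filter_sv_regions,
                     insertions_pass_through, simulate_sv_calls,
                     simulate_sv_truth)
from germpop.sv_consensus import SVRegion


def DEL(sample, start, end, caller="a", support=9, chrom="A01"):
    return IntervalCall(sample, chrom, start, end, "DEL", caller, support,
                        end - start)


def INS(sample, pos, length=80, caller="b", support=9, chrom="A01"):
    return IntervalCall(sample, chrom, pos, pos + 1, "INS", caller, support,
                        length)


class TestConsensus:
    def test_identical_intervals_kept(self):
        out = consensus_deletions([DEL("S1", 100, 300)], [DEL("S1", 100, 300)])
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (100, 300)
        assert out[0].caller == "consensus"

    def test_single_caller_dropped(self):
        assert consensus_deletions([DEL("S1", 100, 300)], []) == []

    def test_partial_overlap_intersection(self):
        # A=[100,300), B=[150,400): reciprocal overlaps 150/200 and 150/250
        out = consensus_deletions([DEL("S1", 100, 300)], [DEL("S1", 150, 400)])
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (150, 300)

    def test_below_reciprocal_threshold_dropped(self):
        # overlap 50 of lengths 200 and 300 -> reciprocal 0.25 and 0.167
        out = consensus_deletions([DEL("S1", 100, 300)], [DEL("S1", 250, 550)])
        assert out == []

    def test_low_support_excluded(self):
        out = consensus_deletions([DEL("S1", 100, 300, support=4)],
                                  [DEL("S1", 100, 300)])
        assert out == []

    def test_one_to_one_matching_greedy(self):
        # two A calls both overlap one B call; only the better match pairs
        a = [DEL("S1", 100, 200), DEL("S1", 140, 240)]
        b = [DEL("S1", 130, 230)]
        out = consensus_deletions(a, b)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (140, 230)

    def test_sample_separation(self):
        out = consensus_deletions([DEL("S1", 100, 300)], [DEL("S2", 100, 300)])
        assert out == []


class TestInsertions:
    def test_support_threshold(self):
        calls = [INS("S1", 500, support=5), INS("S2", 600, support=4)]
        out = insertions_pass_through(calls)
        assert [c.sample for c in out] == ["S1"]

    def test_dels_excluded(self):
        out = insertions_pass_through([DEL("S1", 10, 100), INS("S2", 600)])
        assert [c.sv_type for c in out] == ["INS"]


def oracle_combine(calls):
    """Per-base carrier map -> maximal identical-carrier runs."""
    per_chrom = defaultdict(list)
    for c in calls:
        per_chrom[c.chrom].append(c)
    regions = []
    for chrom, cs in sorted(per_chrom.items()):
        lo = min(c.start for c in cs)
        hi = max(c.end for c in cs)
        carrier_at = []
        for pos in range(lo, hi):
            carr = frozenset(c.sample for c in cs if c.start <= pos < c.end)
            carrier_at.append(carr)
        start = None
        for k, carr in enumerate(carrier_at + [frozenset()]):
            if start is not None and carr != carrier_at[start - lo]:
                if carrier_at[start - lo]:
                    regions.append((chrom, start, lo + k,
                                    carrier_at[start - lo]))
                start = lo + k if carr else None
            elif start is None and carr:
                start = lo + k
    return regions


class TestCombineRegions:
    def test_identical_intervals_merge(self):
        out = combine_regions([DEL("S1", 100, 200), DEL("S2", 100, 200)])
        assert len(out) == 1
        assert out[0].carriers == {"S1", "S2"}

    def test_staggered_three_way_split(self):
        out = combine_regions([DEL("S1", 0, 100), DEL("S2", 50, 150)])
        got = [(r.start, r.end, set(r.carriers)) for r in out]
        assert got == [(0, 50, {"S1"}), (50, 100, {"S1", "S2"}),
                       (100, 150, {"S2"})]

    def test_disjoint_calls_one_region_each(self):
        out = combine_regions([DEL("S1", 0, 50), DEL("S2", 100, 150)])
        assert len(out) == 2

    def test_mixed_types_rejected(self):
        with pytest.raises(ValueError):
            combine_regions([DEL("S1", 0, 50), INS("S2", 100)])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        calls = []
        for i in range(12):
            start = int(rng.integers(0, 400))
            end = start + int(rng.integers(10, 120))
            calls.append(DEL(f"S{rng.integers(5)}", start, end,
                             chrom=("A01" if rng.random() < 0.7 else "C01")))
        got = [(r.chrom, r.start, r.end, r.carriers)
               for r in combine_regions(calls)]
        assert got == oracle_combine(calls)

    def test_partition_property(self):
        rng = np.random.default_rng(11)
        calls = [DEL(f"S{rng.integers(4)}", int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 300, 10),
                                 rng.integers(20, 90, 10))]
        regions = combine_regions(calls)
        covered = set()
        for r in regions:
            span = set(range(r.start, r.end))
            assert not span & covered  # no overlaps between regions
            covered |= span
        input_cover = set()
        for c in calls:
            input_cover |= set(range(c.start, c.end))
        assert covered == input_cover  # union preserved
        for r1, r2 in zip(regions, regions[1:]):
            if r1.end == r2.start and r1.chrom == r2.chrom:
                assert r1.carriers != r2.carriers

    def test_ins_region_length_is_median_of_calls(self):
        out = combine_regions([INS("S1", 500, length=60),
                               INS("S2", 500, length=100)])
        assert out[0].length_bp == 80


class TestFilterRegions:
    def test_length_floor(self):
        short = SVRegion("A01", 0, 49, "DEL", frozenset({"S1", "S2"}), 49)
        ok = SVRegion("A01", 0, 50, "DEL", frozenset({"S1", "S2"}), 50)
        assert filter_sv_regions([short, ok], n_samples=10) == [ok]

    def test_maf_floor(self):
        r = SVRegion("A01", 0, 100, "DEL", frozenset({"S1"}), 100)
        assert filter_sv_regions([r], n_samples=30) == []      # 1/30 < 0.05
        assert filter_sv_regions([r], n_samples=20) == [r]     # 1/20 = 0.05

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_direct_re_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        regions = [SVRegion("A01", 0, 1, "DEL",
                            frozenset(f"S{i}" for i in
                                      rng.choice(20, rng.integers(1, 8),
                                                 replace=False)),
                            int(rng.integers(20, 200)))
                   for _ in range(50)]
        got = filter_sv_regions(regions, n_samples=20)
        expect = [r for r in regions
                  if r.length_bp >= 50 and len(r.carriers) / 20 >= 0.05]
        assert got == expect


class TestAnnotateSvs:
    def _gene(self):
        tx = Transcript("t1", exons=[(100, 250), (350, 500)],
                        cds=[(150, 250), (350, 420)],
                        utr5=[(100, 150)], utr3=[(420, 500)])
        return GeneModel("g1", "A01", "+", [tx])

    def _region(self, start, end, carriers=("S1", "S2"), chrom="A01"):
        return SVRegion(chrom, start, end, "DEL", frozenset(carriers),
                        end - start)

    def test_categories(self):
        index = build_gene_index([self._gene()])
        cases = {
            (0, 50): "intergenic",
            (260, 300): "intron",          # inside the single intron
            (160, 200): "CDS",
            (110, 140): "UTR",
            (400, 450): "CDS+UTR",         # spans CDS/3'UTR junction
        }
        for (s, e), expect in cases.items():
            annotated, _ = annotate_svs({"DEL": [self._region(s, e)]}, index)
            assert annotated["DEL"][0].category == expect, (s, e)

    def test_per_base_truth_table(self):
        gene = self._gene()
        index = build_gene_index([gene])
        tx = gene.transcripts[0]
        for start in range(0, 600, 7):
            region = self._region(start, start + 30)
            annotated, _ = annotate_svs({"DEL": [region]}, index)
            got = annotated["DEL"][0].category
            span = range(start, start + 30)
            in_gene = any(gene.span[0] <= p < gene.span[1] for p in span)
            in_cds = any(s <= p < e for p in span for s, e in tx.cds)
            in_utr = any(s <= p < e for p in span
                         for s, e in tx.utr5 + tx.utr3)
            if not in_gene:
                expect = "intergenic"
            elif in_cds and in_utr:
                expect = "CDS+UTR"
            elif in_cds:
                expect = "CDS"
            elif in_utr:
                expect = "UTR"
            else:
                expect = "intron"
            assert got == expect, start

    def test_summary_totals_and_random_scaffolds(self):
        index = build_gene_index([])
        regions = {"DEL": [self._region(0, 100),
                           self._region(0, 100, chrom="C01"),
                           self._region(0, 100, chrom="A01_random"),
                           self._region(0, 100, chrom="scaffold_9")],
                   "INS": []}
        _, summary = annotate_svs(regions, index)
        tbl = summary.per_chromosome
        assert tbl.loc["Random scaffolds", "DEL"] == 2
        assert tbl["DEL"].sum() == 4
        assert summary.size_stats["DEL"]["min"] == 100
        assert summary.size_stats["DEL"]["median"] == 100

    def test_group_exclusive_and_carrier_fraction(self):
        index = build_gene_index([])
        pm = PopulationMap({"S1": "g1", "S2": "g1", "S3": "g2", "S4": "g2"})
        regions = {"DEL": [self._region(0, 100, carriers=("S1", "S2")),
                           self._region(200, 300, carriers=("S1", "S3"))]}
        _, summary = annotate_svs(regions, index, pm)
        assert summary.exclusive_counts["DEL"] == {"g1": 1, "g2": 0}
        # mean over regions of |carriers in g|/|g|: g1 -> (1.0+0.5)/2
        assert summary.mean_carrier_fraction["DEL"]["g1"] == pytest.approx(0.75)
        assert summary.mean_carrier_fraction["DEL"]["g2"] == pytest.approx(0.25)


class TestSimulatedRecovery:
    def test_noise_free_consensus_equals_truth(self):
        cfg = SimConfig(seed=5, sv_n_deletions=25, sv_n_insertions=8)
        samples = [f"S{i:02d}" for i in range(30)]
        truth = simulate_sv_truth(cfg, samples)
        calls_a, calls_b = simulate_sv_calls(
            truth, samples, fp_rate=0.0, fn_rate=0.0, jitter_bp=0, seed=1)
        cons = consensus_deletions(calls_a, calls_b)
        truth_dels = {(r.chrom, r.start, r.end, s)
                      for r in truth if r.sv_type == "DEL"
                      for s in r.carriers}
        got = {(c.chrom, c.start, c.end, c.sample) for c in cons}
        assert got == truth_dels
        regions = combine_regions(cons)
        got_regions = {(r.chrom, r.start, r.end, r.carriers) for r in regions}
        expect_regions = {(r.chrom, r.start, r.end, r.carriers)
                          for r in truth if r.sv_type == "DEL"}
        assert got_regions == expect_regions

    def test_total_caller_a_dropout_empties_consensus(self):
        cfg = SimConfig(seed=6, sv_n_deletions=10, sv_n_insertions=0)
        samples = [f"S{i}" for i in range(10)]
        truth = simulate_sv_truth(cfg, samples)
        calls_a, calls_b = simulate_sv_calls(
            truth, samples, fp_rate=0.0, fn_rate=0.0, jitter_bp=0, seed=1)
        assert consensus_deletions([], calls_b) == []

    def test_insertions_only_from_caller_b(self):
        cfg = SimConfig(seed=8, sv_n_deletions=5, sv_n_insertions=10)
        samples = [f"S{i}" for i in range(10)]
        truth = simulate_sv_truth(cfg, samples)
        calls_a, calls_b = simulate_sv_calls(
            truth, samples, fp_rate=0.0, fn_rate=0.0, jitter_bp=0, seed=1)
        assert all(c.sv_type == "DEL" for c in calls_a)
        assert any(c.sv_type == "INS" for c in calls_b)

    def test_precision_degrades_with_fp_rate(self):
        cfg = SimConfig(seed=9, sv_n_deletions=20, sv_n_insertions=0)
        samples = [f"S{i}" for i in range(25)]
        truth = simulate_sv_truth(cfg, samples)
        truth_keys = {(r.chrom, r.start, r.end, s)
                      for r in truth if r.sv_type == "DEL"
                      for s in r.carriers}
        precisions = []
        for fp in (0.0, 2.0, 8.0):
            vals = []
            for seed in range(4):
                a, b = simulate_sv_calls(
                    truth, samples, fp_rate=fp, fn_rate=0.0, jitter_bp=0,
                    seed=seed, chromosome_lengths=cfg.chromosome_lengths)
                cons = consensus_deletions(a, b)
                if not cons:
                    continue
                tp = sum((c.chrom, c.start, c.end, c.sample) in truth_keys
                         for c in cons)
                vals.append(tp / len(cons))
            precisions.append(np.mean(vals))
        assert precisions[0] == 1.0
        assert precisions[0] >= precisions[1] >= precisions[2]
        assert precisions[2] < 1.0
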