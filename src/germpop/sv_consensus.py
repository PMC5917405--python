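"""Two-caller structural-variant consensus, multi-sample region combination,
length/frequency filtering, genic annotation and summary tables.

Deletions require confirmation by both callers (reciprocal overlap within
the same sample); insertions are taken from the single caller that reports
them.  Per-sample consensus calls are then combined across samples by
partitioning the genome at every interval endpoint — the multi-intersect
operation — and maximal runs with identical carrier sets become SVRegions.
"""

from __future__ import annotations

import statistics
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .effect_annotation import GeneIndex
from .formats_io import IntervalCall, PopulationMap
from .variant_filter import subgenome_of

RANDOM_SCAFFOLD_BUCKET = "Random scaffolds"

SV_CATEGORIES = ("intergenic", "intron", "CDS", "UTR", "CDS+UTR")


@dataclass(frozen=True)
class SVRegion:
    """A multi-sample region of structural variation (half-open coords)."""

    chrom: str
    start: int
    end: int
    sv_type: str
    carriers: frozenset[str]
    length_bp: int
    category: str | None = None
    genes: tuple[str, ...] = ()

    def carrier_maf(self, n_samples: int) -> float:
        return len(self.carriers) / n_samples


@dataclass
class SVSummary:
    per_chromosome: pd.DataFrame          # index chrom/bucket, DEL/INS columns
    size_stats: dict[str, dict[str, float]]
    exclusive_counts: dict[str, dict[str, int]]   # sv_type -> group -> count
    mean_carrier_fraction: dict[str, dict[str, float]]
    category_counts: dict[str, dict[str, int]]    # sv_type -> category -> n


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def _overlap(a: IntervalCall, b: IntervalCall) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _reciprocal(a: IntervalCall, b: IntervalCall) -> float:
    ov = _overlap(a, b)
    if ov == 0:
        return 0.0
    return min(ov / (a.end - a.start), ov / (b.end - b.start))


def consensus_deletions(calls_a: Sequence[IntervalCall],
                        calls_b: Sequence[IntervalCall],
                        min_reciprocal_overlap: float = 0.5,
                        min_support: int = 5) -> list[IntervalCall]:
    """Per-sample deletion consensus between two callers.

    A caller-A deletion survives iff a caller-B deletion in the same sample
    overlaps it with reciprocal overlap >= threshold; pairs are matched
    greedily by descending overlap (ties to the leftmost pair) and each
    call matches at most once.  The consensus interval is the intersection
    of the matched pair; support is the smaller of the two.
    """
    by_sample_a: dict[tuple[str, str], list[IntervalCall]] = defaultdict(list)
    by_sample_b: dict[tuple[str, str], list[IntervalCall]] = defaultdict(list)
    for c in calls_a:
        if c.sv_type == "DEL" and c.support >= min_support:
            by_sample_a[(c.sample, c.chrom)].append(c)
    for c in calls_b:
        if c.sv_type == "DEL" and c.support >= min_support:
            by_sample_b[(c.sample, c.chrom)].append(c)

    out: list[IntervalCall] = []
    for key in sorted(by_sample_a):
        aa = sorted(by_sample_a[key], key=lambda c: (c.start, c.end))
        bb = sorted(by_sample_b.get(key, []), key=lambda c: (c.start, c.end))
        candidates = []
        for ia, a in enumerate(aa):
            for ib, b in enumerate(bb):
                ro = _reciprocal(a, b)
                if ro >= min_reciprocal_overlap:
                    candidates.append((-ro, a.start, b.start, ia, ib))
        candidates.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _ro, _as, _bs, ia, ib in candidates:
            if ia in used_a or ib in used_b:
                continue
            used_a.add(ia)
            used_b.add(ib)
            a, b = aa[ia], bb[ib]
            s, e = max(a.start, b.start), min(a.end, b.end)
            out.append(IntervalCall(
                sample=a.sample, chrom=a.chrom, start=s, end=e, sv_type="DEL",
                caller="consensus", support=min(a.support, b.support),
                length=e - s,
            ))
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample))
    return out


def insertions_pass_through(calls_b: Sequence[IntervalCall],
                            min_support: int = 5) -> list[IntervalCall]:
    """Single-caller insertions with sufficient read support, unchanged."""
    out = [c for c in calls_b if c.sv_type == "INS" and c.support >= min_support]
    return sorted(out, key=lambda c: (c.chrom, c.start, c.sample))


# ---------------------------------------------------------------------------
# Multi-sample combination
# ---------------------------------------------------------------------------

def combine_regions(per_sample_calls: Sequence[IntervalCall]) -> list[SVRegion]:
    """Partition the genome at every call endpoint into carrier-homogeneous
    regions (the multi-intersect operation), merging adjacent pieces with
    identical carrier sets.

    All calls must share one ``sv_type``.  For insertions, whose calls are
    anchor points, the region length is the median of the carriers' reported
    inserted-sequence lengths; for deletions it is the region span.
    """
    if not per_sample_calls:
        return []
    sv_types = {c.sv_type for c in per_sample_calls}
    if len(sv_types) != 1:
        raise ValueError(f"combine_regions requires a single sv_type, got {sv_types}")
    sv_type = sv_types.pop()

    by_chrom: dict[str, list[IntervalCall]] = defaultdict(list)
    for c in per_sample_calls:
        by_chrom[c.chrom].append(c)

    regions: list[SVRegion] = []
    for chrom in sorted(by_chrom):
        calls = by_chrom[chrom]
        points = sorted({p for c in calls for p in (c.start, c.end)})
        pieces: list[tuple[int, int, frozenset[str]]] = []
        for s, e in zip(points, points[1:]):
            carriers = frozenset(c.sample for c in calls if c.start <= s and c.end >= e)
            if carriers:
                pieces.append((s, e, carriers))
        # merge contiguous pieces with identical carrier sets
        merged: list[tuple[int, int, frozenset[str]]] = []
        for s, e, carr in pieces:
            if merged and merged[-1][1] == s and merged[-1][2] == carr:
                merged[-1] = (merged[-1][0], e, carr)
            else:
                merged.append((s, e, carr))
        for s, e, carr in merged:
            if sv_type == "INS":
                lens = [c.length for c in calls
                        if c.sample in carr and s < c.end and c.start < e]
                length = int(round(statistics.median(lens)))
            else:
                length = e - s
            regions.append(SVRegion(chrom=chrom, start=s, end=e, sv_type=sv_type,
                                    carriers=carr, length_bp=length))
    return regions


def filter_sv_regions(regions: Sequence[SVRegion], n_samples: int,
                      min_length: int = 50,
                      min_maf: float = 0.05) -> list[SVRegion]:
    """Keep regions with length >= ``min_length`` bp and carrier frequency
    >= ``min_maf`` over all samples."""
    return [r for r in regions
            if r.length_bp >= min_length and r.carrier_maf(n_samples) >= min_maf]


# ---------------------------------------------------------------------------
# Annotation and summary
# ---------------------------------------------------------------------------

def _sv_category(region: SVRegion, index: GeneIndex) -> tuple[str, tuple[str, ...]]:
    hit_cds = hit_utr = hit_gene = False
    genes: list[str] = []
    chrom_entry = index._chrom.get(region.chrom)
    if chrom_entry is None:
        return "intergenic", ()
    starts, ends, gene_list = chrom_entry
    for i, g in enumerate(gene_list):
        if ends[i] <= region.start or starts[i] >= region.end:
            continue
        hit_gene = True
        genes.append(g.gene_id)
        for tx in g.transcripts:
            for s, e in tx.cds:
                if s < region.end and region.start < e:
                    hit_cds = True
            for s, e in list(tx.utr5) + list(tx.utr3):
                if s < region.end and region.start < e:
                    hit_utr = True
    if not hit_gene:
        return "intergenic", ()
    if hit_cds and hit_utr:
        return "CDS+UTR", tuple(genes)
    if hit_cds:
        return "CDS", tuple(genes)
    if hit_utr:
        return "UTR", tuple(genes)
    return "intron", tuple(genes)


def annotate_svs(regions_by_type: Mapping[str, Sequence[SVRegion]],
                 index: GeneIndex,
                 popmap: PopulationMap | None = None,
                 ) -> tuple[dict[str, list[SVRegion]], SVSummary]:
    """Assign each region a genic-overlap category and build the summary.

    ``regions_by_type`` maps 'DEL'/'INS' to filtered region lists.  Group
    exclusivity (all carriers drawn from one group) and mean carrier
    fraction are computed when a population map is supplied.
    """
    annotated: dict[str, list[SVRegion]] = {}
    for sv_type, regions in regions_by_type.items():
        annotated[sv_type] = [
            replace(r, category=cat, genes=genes)
            for r in regions
            for cat, genes in [_sv_category(r, index)]
        ]

    chrom_rows: dict[str, dict[str, int]] = defaultdict(lambda: {"DEL": 0, "INS": 0})
    size_stats: dict[str, dict[str, float]] = {}
    category_counts: dict[str, dict[str, int]] = {}
    exclusive: dict[str, dict[str, int]] = {}
    carrier_frac: dict[str, dict[str, float]] = {}

    groups = popmap.groups if popmap is not None else []
    members = {g: {s for s, gg in popmap.assignment.items() if gg == g}
               for g in groups} if popmap else {}

    for sv_type, regions in annotated.items():
        for r in regions:
            bucket = r.chrom if subgenome_of(r.chrom) in ("A", "C") \
                else RANDOM_SCAFFOLD_BUCKET
            chrom_rows[bucket][sv_type] += 1
        sizes = [r.length_bp for r in regions]
        size_stats[sv_type] = {
            "min": float(min(sizes)) if sizes else float("nan"),
            "median": float(statistics.median(sizes)) if sizes else float("nan"),
            "max": float(max(sizes)) if sizes else float("nan"),
            "n": len(sizes),
        }
        category_counts[sv_type] = {c: 0 for c in SV_CATEGORIES}
        for r in regions:
            category_counts[sv_type][r.category] += 1
        if popmap is not None:
            exclusive[sv_type] = {
                g: sum(1 for r in regions if r.carriers and r.carriers <= members[g])
                for g in groups
            }
            carrier_frac[sv_type] = {
                g: (sum(len(r.carriers & members[g]) / len(members[g])
                        for r in regions) / len(regions)) if regions else float("nan")
                for g in groups
            }

    order = sorted(chrom_rows, key=lambda c: (c == RANDOM_SCAFFOLD_BUCKET, c))
    per_chrom = pd.DataFrame(
        [{"chromosome": c, "DEL": chrom_rows[c]["DEL"], "INS": chrom_rows[c]["INS"]}
         for c in order]
    ).set_index("chromosome") if chrom_rows else pd.DataFrame(columns=["DEL", "INS"])

    summary = SVSummary(
        per_chromosome=per_chrom,
        size_stats=size_stats,
        exclusive_counts=exclusive,
        mean_carrier_fraction=carrier_frac,
        category_counts=category_counts,
    )
    return annotated, summary
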