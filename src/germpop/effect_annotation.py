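"""SnpEff-style functional classification of SNPs against gene models.

Each SNP receives exactly one category after severity resolution across all
overlapping transcripts; per-transcript effects are retained in the detailed
output.  Splice donor/acceptor sites are the first/last 2 bp of an intron in
transcription order (the canonical GT/AG dinucleotides).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .formats_io import GeneModel, Locus, Transcript

CATEGORIES = (
    "intergenic", "intron", "splice_acceptor", "splice_donor", "utr5", "utr3",
    "synonymous", "non_synonymous", "stop_gained", "stop_lost", "start_lost",
)

#: Severity rank for cross-transcript resolution (higher = more severe).
SEVERITY = {
    "start_lost": 6, "stop_gained": 6, "stop_lost": 6,
    "non_synonymous": 5, "synonymous": 4,
    "splice_acceptor": 3, "splice_donor": 3,
    "utr5": 2, "utr3": 2, "intron": 1, "intergenic": 0,
}

SPLICE_REGION_BP = 2

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = set(standard_dna_table.stop_codons)


@dataclass
class SnpEffect:
    locus: Locus
    category: str
    gene_id: str | None = None
    transcript_status: str = "ok"
    per_transcript: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown effect category {self.category!r}")


# ---------------------------------------------------------------------------
# Gene index
# ---------------------------------------------------------------------------

class GeneIndex:
    """Point-queryable index over gene spans (0-based half-open internally)."""

    def __init__(self, models: Iterable[GeneModel]):
        per_chrom: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for g in models:
            s, e = g.span
            per_chrom.setdefault(g.chrom, []).append((s, e, g))
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, list[GeneModel]]] = {}
        for chrom, entries in per_chrom.items():
            entries.sort(key=lambda t: t[0])
            starts = np.array([s for s, _, _ in entries], dtype=np.int64)
            ends = np.array([e for _, e, _ in entries], dtype=np.int64)
            self._chrom[chrom] = (starts, ends, [g for _, _, g in entries])

    def genes_at(self, chrom: str, pos0: int) -> list[GeneModel]:
        """All genes whose span covers 0-based position ``pos0``."""
        entry = self._chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, genes = entry
        hit = (starts <= pos0) & (ends > pos0)
        return [genes[i] for i in np.flatnonzero(hit)]

    def all_genes(self) -> list[GeneModel]:
        return [g for _, _, gs in self._chrom.values() for g in gs]


def build_gene_index(models: Iterable[GeneModel]) -> GeneIndex:
    return GeneIndex(models)


def _in_segments(pos0: int, segments: Sequence[tuple[int, int]]) -> bool:
    i = bisect_right(segments, (pos0, np.inf)) - 1
    return i >= 0 and segments[i][0] <= pos0 < segments[i][1]


# ---------------------------------------------------------------------------
# Per-transcript classification
# ---------------------------------------------------------------------------

def _splice_or_intron(pos0: int, tx: Transcript, strand: str) -> str | None:
    for s, e in tx.introns():
        if not s <= pos0 < e:
            continue
        first = pos0 < s + SPLICE_REGION_BP         # 2 bp at genomic left end
        last = pos0 >= e - SPLICE_REGION_BP
        if first:
            return "splice_donor" if strand == "+" else "splice_acceptor"
        if last:
            return "splice_acceptor" if strand == "+" else "splice_donor"
        return "intron"
    return None


def _coding_effect(pos0: int, locus: Locus, tx: Transcript, strand: str,
                   reference: Mapping[str, str]) -> tuple[str, str]:
    """(category, status) for a position inside a CDS segment."""
    chrom_seq = reference[locus.chrom]
    genomic_cds = "".join(chrom_seq[s:e] for s, e in tx.cds)
    offset = 0
    for s, e in tx.cds:
        if s <= pos0 < e:
            offset += pos0 - s
            break
        offset += e - s
    if strand == "+":
        coding = genomic_cds
        cds_index = offset
        alt = locus.alt_allele
    else:
        coding = genomic_cds.translate(_COMPLEMENT)[::-1]
        cds_index = len(coding) - 1 - offset
        alt = locus.alt_allele.translate(_COMPLEMENT)

    status = "ok" if tx.cds_complete else "incomplete"
    codon_idx = cds_index // 3
    within = cds_index % 3
    if codon_idx * 3 + 3 > len(coding):
        # truncated tail codon of an incomplete transcript: untranslatable
        return "synonymous", "incomplete"
    ref_codon = coding[codon_idx * 3: codon_idx * 3 + 3]
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1:]
    if codon_idx == 0 and alt_codon != ref_codon:
        return "start_lost", status
    ref_stop = ref_codon in _STOPS
    alt_stop = alt_codon in _STOPS
    if ref_stop and not alt_stop:
        return "stop_lost", status
    if alt_stop and not ref_stop:
        return "stop_gained", status
    if ref_stop and alt_stop:
        return "synonymous", status
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return ("synonymous" if ref_aa == alt_aa else "non_synonymous"), status


def _utr_side(pos0: int, tx: Transcript, strand: str) -> str:
    """utr5/utr3 for an exonic, non-CDS position, inferred from the CDS span
    when no annotated UTR segment covers the position."""
    if _in_segments(pos0, tx.utr5):
        return "utr5"
    if _in_segments(pos0, tx.utr3):
        return "utr3"
    if tx.cds:
        before_cds = pos0 < tx.cds[0][0]
        if strand == "+":
            return "utr5" if before_cds else "utr3"
        return "utr3" if before_cds else "utr5"
    return "utr5"  # UTR-only transcript: side undefined, flagged by caller


def classify_in_transcript(pos0: int, locus: Locus, tx: Transcript, strand: str,
                           reference: Mapping[str, str]) -> tuple[str, str] | None:
    """(category, status) for one transcript, or None when outside its span."""
    span_s, span_e = tx.span
    if not span_s <= pos0 < span_e:
        return None
    if _in_segments(pos0, tx.exons):
        if _in_segments(pos0, tx.cds):
            # for a non-triplet CDS the effect is still computed codon-wise
            # where the codon is intact, but carries an 'incomplete' status
            return _coding_effect(pos0, locus, tx, strand, reference)
        side = _utr_side(pos0, tx, strand)
        status = "ok" if tx.is_coding else "incomplete"
        return side, status
    hit = _splice_or_intron(pos0, tx, strand)
    if hit is not None:
        return hit, "ok"
    return None


def classify_snp(locus: Locus, index: GeneIndex,
                 reference: Mapping[str, str]) -> SnpEffect:
    """Classify one SNP; the most severe category across transcripts wins."""
    chrom_seq = reference.get(locus.chrom)
    pos0 = locus.pos - 1
    if chrom_seq is None or pos0 >= len(chrom_seq):
        raise ValueError(f"locus {locus.chrom}:{locus.pos} outside reference")
    if chrom_seq[pos0] != locus.ref_allele:
        raise ValueError(
            f"reference mismatch at {locus.chrom}:{locus.pos}: "
            f"reference has {chrom_seq[pos0]!r}, locus says {locus.ref_allele!r}"
        )
    hits: list[tuple[str, str, str, str]] = []  # (category, status, gene, tx)
    for gene in index.genes_at(locus.chrom, pos0):
        for tx in gene.transcripts:
            res = classify_in_transcript(pos0, locus, tx, gene.strand, reference)
            if res is not None:
                hits.append((res[0], res[1], gene.gene_id, tx.transcript_id))
    if not hits:
        return SnpEffect(locus=locus, category="intergenic")
    hits.sort(key=lambda h: (-SEVERITY[h[0]], h[2], h[3]))
    category, status, gene_id, _ = hits[0]
    return SnpEffect(
        locus=locus, category=category, gene_id=gene_id,
        transcript_status=status,
        per_transcript=[(tx, cat) for cat, _st, _g, tx in hits],
    )


# ---------------------------------------------------------------------------
# Whole-set annotation and summary
# ---------------------------------------------------------------------------

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}

GENIC_CATEGORIES = tuple(c for c in CATEGORIES if c != "intergenic")


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage on the 0-100 scale, rounded for reporting (e.g. 68.8)."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * numerator / denominator, decimals)


def is_transition(locus: Locus) -> bool:
    return frozenset((locus.ref_allele, locus.alt_allele)) in _TRANSITIONS


def annotate_all(loci: Sequence[Locus], index: GeneIndex,
                 reference: Mapping[str, str],
                 ) -> tuple[list[SnpEffect], dict]:
    """Annotate every SNP and compute the category/Ts-Tv summary.

    The summary reports category counts, fractions of the genic total, the
    genic/intergenic split, genes containing >=1 SNP, and the
    transition/transversion split.  The splice fraction is reported against
    both the genic and the intronic denominator (the latter including
    splice-site SNPs themselves).
    """
    effects = [classify_snp(loc, index, reference) for loc in loci]
    counts = {c: 0 for c in CATEGORIES}
    genes_hit: set[str] = set()
    ts = 0
    for eff in effects:
        counts[eff.category] += 1
        if eff.gene_id is not None:
            genes_hit.add(eff.gene_id)
        if is_transition(eff.locus):
            ts += 1
    total = len(effects)
    genic = total - counts["intergenic"]
    tv = total - ts
    splice = counts["splice_acceptor"] + counts["splice_donor"]
    intronic = counts["intron"] + splice
    summary = {
        "n_snps": total,
        "n_genic": genic,
        "n_intergenic": counts["intergenic"],
        "pct_intergenic": percent(counts["intergenic"], total),
        "counts": counts,
        "pct_of_genic": {c: percent(counts[c], genic) for c in GENIC_CATEGORIES},
        "pct_splice_of_genic": percent(splice, genic),
        "pct_splice_of_intronic": percent(splice, intronic),
        "genes_with_snp": len(genes_hit),
        "transitions": ts,
        "transversions": tv,
        "ts_tv_ratio": (ts / tv) if tv else float("nan"),
    }
    return effects, summary


def effects_table(effects: Sequence[SnpEffect]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [e.locus.chrom for e in effects],
        "pos": [e.locus.pos for e in effects],
        "ref": [e.locus.ref_allele for e in effects],
        "alt": [e.locus.alt_allele for e in effects],
        "category": [e.category for e in effects],
        "gene_id": [e.gene_id or "." for e in effects],
        "transcript_status": [e.transcript_status for e in effects],
    })
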