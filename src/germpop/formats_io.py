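"""Readers, writers and shared domain types for the pipeline's external formats.

Coordinate conventions
----------------------
SNP loci keep their VCF-style 1-based position.  All *intervals* (gene
features, SV calls) are held internally as 0-based half-open ``[start, end)``
and converted at the I/O boundary: GFF3 is 1-based inclusive on disk, SV call
TSVs declare their dialect in a ``#dialect=`` header line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Locus:
    """A biallelic SNP site: single-base ref/alt at a 1-based position."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"Locus position must be >= 1, got {self.pos}")
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"Locus alleles must be single A/C/G/T bases, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class GenotypeMatrix:
    """Samples x loci dosage matrix with per-call read depth.

    ``calls[i, j]`` counts alt alleles (0/1/2) for sample *i* at locus *j*,
    or :data:`MISSING`.  ``depths`` holds the raw per-call read depth; the
    depth of a MISSING call is excluded from per-locus depth statistics.
    """

    samples: list[str]
    loci: list[Locus]
    calls: np.ndarray
    depths: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        shape = (len(self.samples), len(self.loci))
        if self.calls.shape != shape or self.depths.shape != shape:
            raise ValueError(
                f"calls/depths shape {self.calls.shape}/{self.depths.shape} "
                f"does not match {shape}"
            )
        keys = [(l.chrom, l.pos) for l in self.loci]
        if keys != sorted(keys):
            raise ValueError("loci must be sorted by (chrom, pos)")
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) among loci")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def positions(self) -> np.ndarray:
        return np.array([l.pos for l in self.loci], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([l.chrom for l in self.loci])

    def subset_loci(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.int64)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            depths=self.depths[:, idx].copy(),
        )

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[n] for n in names], dtype=np.int64)
        return GenotypeMatrix(
            samples=list(names),
            loci=list(self.loci),
            calls=self.calls[idx, :].copy(),
            depths=self.depths[idx, :].copy(),
        )


@dataclass
class PopulationMap:
    """Sample -> group-label assignment."""

    assignment: dict[str, str]

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def group_of(self, sample: str) -> str:
        return self.assignment[sample]

    def indices_by_group(self, samples: Sequence[str]) -> dict[str, np.ndarray]:
        """Row indices into ``samples`` per group; every sample must be mapped."""
        missing = [s for s in samples if s not in self.assignment]
        if missing:
            raise KeyError(f"samples without a group assignment: {missing[:5]}")
        out: dict[str, list[int]] = {}
        for i, s in enumerate(samples):
            out.setdefault(self.assignment[s], []).append(i)
        return {g: np.array(ix, dtype=np.int64) for g, ix in out.items()}


@dataclass
class Transcript:
    """Transcript-level gene structure; all intervals 0-based half-open,
    stored in genomic order regardless of strand."""

    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def sort(self) -> None:
        for seg in (self.exons, self.cds, self.utr5, self.utr3):
            seg.sort()

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_complete(self) -> bool:
        """True when the concatenated CDS length is a codon multiple."""
        return self.is_coding and self.cds_length % 3 == 0

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return out

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return min(starts), max(ends)


@dataclass(frozen=True)
class IntervalCall:
    """One per-sample SV call from one caller; internal half-open coords.

    For insertions the interval is an anchor point (``end == start + 1``)
    and ``length`` carries the reported inserted-sequence length; for
    deletions ``length`` equals the interval span.
    """

    sample: str
    chrom: str
    start: int
    end: int
    sv_type: str
    caller: str
    support: int
    length: int

    def __post_init__(self) -> None:
        if self.sv_type not in ("DEL", "INS"):
            raise ValueError(f"sv_type must be DEL or INS, got {self.sv_type}")
        if self.sv_type == "DEL" and self.end <= self.start:
            raise ValueError("DEL interval must have end > start")
        if self.support < 0:
            raise ValueError("support must be >= 0")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, min_depth_for_call: int = 0) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are skipped (counted in
    ``matrix.meta``).  A call becomes MISSING when any allele is ``.`` or,
    if ``min_depth_for_call`` > 0, when its DP is below that threshold.
    Half-missing genotypes such as ``0/.`` are treated as MISSING and
    counted separately.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[Locus] = []
    call_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    skipped_multiallelic = 0
    skipped_non_snp = 0
    half_missing = 0

    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped_multiallelic += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            skipped_non_snp += 1
            continue
        dosages = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a = gt[:-1]  # last element is the phased flag
            if len(a) < 2 or -1 in a:
                if len(a) >= 2 and (a[0] == -1) != (a[1] == -1):
                    half_missing += 1
                continue
            dosages[i] = int(a[0] > 0) + int(a[1] > 0)
        dp = rec.format("DP")
        if dp is None:
            depths = np.zeros(len(samples), dtype=np.int32)
        else:
            depths = dp[:, 0].astype(np.int32)
            depths[depths < 0] = 0
        if min_depth_for_call > 0:
            dosages[depths < min_depth_for_call] = MISSING
        loci.append(Locus(rec.CHROM, rec.POS, ref, alt))
        call_rows.append(dosages)
        depth_rows.append(depths)

    if skipped_multiallelic or skipped_non_snp:
        logger.info(
            "read_vcf(%s): skipped %d multi-allelic and %d non-SNP records",
            path, skipped_multiallelic, skipped_non_snp,
        )
    if half_missing:
        logger.info("read_vcf(%s): %d half-missing genotypes set to MISSING",
                    path, half_missing)
    if not loci:
        logger.warning("read_vcf(%s): zero retained loci", path)
        matrix = GenotypeMatrix(samples, [], np.empty((len(samples), 0)),
                                np.empty((len(samples), 0)))
    else:
        order = sorted(range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].pos))
        matrix = GenotypeMatrix(
            samples,
            [loci[i] for i in order],
            np.stack([call_rows[i] for i in order], axis=1),
            np.stack([depth_rows[i] for i in order], axis=1),
        )
    matrix.meta.update(
        skipped_multiallelic=skipped_multiallelic,
        skipped_non_snp=skipped_non_snp,
        half_missing=half_missing,
    )
    return matrix


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Serialize a GenotypeMatrix as minimal VCF 4.2 with GT and DP."""
    path = Path(path)
    dosage_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in dict.fromkeys(l.chrom for l in matrix.loci):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for j, loc in enumerate(matrix.loci):
            cells = [
                f"{dosage_to_gt[int(matrix.calls[i, j])]}:{int(matrix.depths[i, j])}"
                for i in range(matrix.n_samples)
            ]
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t.\t{loc.ref_allele}\t{loc.alt_allele}"
                f"\t.\t.\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path) -> PopulationMap:
    """Two-column TSV: sample <tab> group.  Header line optional."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"popmap line lacks two columns: {line!r}")
            if parts[0].lower() == "sample" and parts[1].lower() in ("group", "population"):
                continue
            assignment[parts[0]] = parts[1]
    return PopulationMap(assignment)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in popmap.assignment.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_UTR5_TYPES = {"five_prime_UTR", "5UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "3UTR", "three_prime_utr"}
_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def _gff3_attrs(col9: str) -> dict[str, str]:
    out = {}
    for part in col9.strip().split(";"):
        if not part:
            continue
        key, _, val = part.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS/UTR features into hierarchical GeneModels.

    GFF3 coordinates (1-based inclusive) are converted to internal 0-based
    half-open.  Features whose Parent is unknown are dropped with a warning;
    a line with the wrong column count is fatal and names the line number.
    """
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, Transcript] = {}
    tx_gene: dict[str, str] = {}
    pending: list[tuple[str, str, int, int]] = []  # (type, parent, start, end)
    dropped = 0

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = cols
            start, end = int(start_s) - 1, int(end_s)  # to half-open
            attrs = _gff3_attrs(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID", f"gene_{lineno}")
                genes[gid] = GeneModel(gene_id=gid, chrom=chrom, strand=strand)
            elif ftype in _TRANSCRIPT_TYPES:
                tid = attrs.get("ID", f"tx_{lineno}")
                parent = attrs.get("Parent", "")
                if parent not in genes:
                    logger.warning("read_gff3: transcript %s has unknown parent %s; dropped",
                                   tid, parent)
                    dropped += 1
                    continue
                tx = Transcript(transcript_id=tid)
                transcripts[tid] = tx
                tx_gene[tid] = parent
                genes[parent].transcripts.append(tx)
            elif ftype in ({"exon", "CDS", "UTR"} | _UTR5_TYPES | _UTR3_TYPES):
                pending.append((ftype, attrs.get("Parent", ""), start, end))

    for ftype, parent, start, end in pending:
        tx = transcripts.get(parent)
        if tx is None:
            logger.warning("read_gff3: %s feature has unknown parent %r; dropped",
                           ftype, parent)
            dropped += 1
            continue
        if ftype == "exon":
            tx.exons.append((start, end))
        elif ftype == "CDS":
            tx.cds.append((start, end))
        elif ftype in _UTR5_TYPES:
            tx.utr5.append((start, end))
        elif ftype in _UTR3_TYPES:
            tx.utr3.append((start, end))
        else:  # generic UTR: side resolved against CDS below
            tx.utr5.append((start, end))  # provisional; re-sided after sort

    models = [g for g in genes.values() if g.transcripts]
    for g in models:
        for tx in g.transcripts:
            tx.sort()
            _reside_generic_utrs(tx, g.strand)
    if dropped:
        logger.info("read_gff3(%s): dropped %d features with unknown parents",
                    path, dropped)
    return models


def _reside_generic_utrs(tx: Transcript, strand: str) -> None:
    """Move provisional UTR segments to the correct side relative to the CDS."""
    if not tx.cds:
        return
    cds_start = tx.cds[0][0]
    cds_end = tx.cds[-1][1]
    keep5, move3 = [], []
    for s, e in tx.utr5:
        if s >= cds_end:
            (move3 if strand == "+" else keep5).append((s, e))
        elif e <= cds_start:
            (keep5 if strand == "+" else move3).append((s, e))
        else:
            keep5.append((s, e))
    if move3:
        tx.utr5 = sorted(keep5)
        tx.utr3 = sorted(tx.utr3 + move3)
    else:
        tx.utr5 = sorted(keep5)


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Serialize GeneModels back to 1-based inclusive GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            gs, ge = g.span
            fh.write(f"{g.chrom}\tgermpop\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            for tx in g.transcripts:
                ts, te = tx.span
                fh.write(f"{g.chrom}\tgermpop\tmRNA\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t"
                         f"ID={tx.transcript_id};Parent={g.gene_id}\n")
                for kind, segs in (("exon", tx.exons), ("CDS", tx.cds),
                                   ("five_prime_UTR", tx.utr5),
                                   ("three_prime_UTR", tx.utr3)):
                    for s, e in segs:
                        fh.write(f"{g.chrom}\tgermpop\t{kind}\t{s + 1}\t{e}\t.\t"
                                 f"{g.strand}\t.\tParent={tx.transcript_id}\n")


# ---------------------------------------------------------------------------
# SV call TSV
# ---------------------------------------------------------------------------

SV_DIALECTS = ("0-based-half-open", "1-based-inclusive")


def read_sv_calls(path: str | Path, caller_label: str) -> list[IntervalCall]:
    """Read per-sample SV calls from a dialect-declaring TSV.

    The first non-empty line must be ``#dialect=<d>`` with *d* one of
    :data:`SV_DIALECTS`; then a header row ``sample chrom start end sv_type
    support [length]``.  DEL rows with a non-positive span are rejected with
    a warning.
    """
    calls: list[IntervalCall] = []
    dialect = None
    header: list[str] | None = None
    rejected = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("#dialect="):
                dialect = line.split("=", 1)[1].strip()
                if dialect not in SV_DIALECTS:
                    raise ValueError(f"unknown SV TSV dialect {dialect!r}")
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = [p.lower() for p in parts]
                continue
            if dialect is None:
                raise ValueError(f"{path}: missing '#dialect=' header line")
            row = dict(zip(header, parts))
            start, end = int(row["start"]), int(row["end"])
            if dialect == "1-based-inclusive":
                start, end = start - 1, end  # to half-open
            sv_type = row["sv_type"].upper()
            if sv_type == "DEL" and end <= start:
                logger.warning("read_sv_calls: rejected DEL with end <= start: %r", line)
                rejected += 1
                continue
            length = int(row["length"]) if "length" in row else end - start
            calls.append(IntervalCall(
                sample=row["sample"], chrom=row["chrom"], start=start, end=end,
                sv_type=sv_type, caller=caller_label,
                support=int(row["support"]), length=length,
            ))
    if rejected:
        logger.info("read_sv_calls(%s): rejected %d malformed rows", path, rejected)
    return calls


def write_sv_calls(calls: Iterable[IntervalCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#dialect=0-based-half-open\n")
        fh.write("sample\tchrom\tstart\tend\tsv_type\tsupport\tlength\n")
        for c in calls:
            fh.write(f"{c.sample}\t{c.chrom}\t{c.start}\t{c.end}\t{c.sv_type}"
                     f"\t{c.support}\t{c.length}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, precision: int = 6) -> str:
    """Newick text with branch lengths at fixed precision."""
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = round(float(edge.length), precision)
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()
    return text


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)
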