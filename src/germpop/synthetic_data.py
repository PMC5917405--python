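"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates the salient features of a re-sequenced allopolyploid
germplasm panel: sub-populations drifted apart from a common ancestral
allele frequency (Balding–Nichols island model with a single divergence
parameter F), group-private alleles, loci with inflated heterozygosity
mimicking homoeologous read misalignment, chromosome-local LD blocks,
strand-aware gene models on a random reference, and noisy two-caller SV
calls over a shared truth set of deletions and insertions.

Every stochastic output is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .formats_io import (MISSING, GeneModel, GenotypeMatrix, IntervalCall,
                         Locus, PopulationMap, Transcript)
from .sv_consensus import SVRegion

_BASES = np.array(list("ACGT"))
_STOP_CODONS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Stated world of the synthetic panel.

    Defaults mirror the re-sequencing panel the pipeline targets: two
    groups sized 94 (local spring types) and 55 (global diversity panel),
    drift F = 0.2, ~10x read depth, a 0.8 heterozygote rate at homoeolog
    artifact loci, and deletion/insertion size distributions matching the
    reported ranges (deletions 50 bp – 15.4 kb, median ≈ 88 bp; insertions
    50–132 bp).
    """

    seed: int
    n_groups: int = 2
    samples_per_group: tuple[int, ...] = (94, 55)
    group_names: tuple[str, ...] = ("australian_spring", "global_diversity")
    n_loci_per_chrom: int = 400
    chromosome_lengths: dict[str, int] = field(default_factory=lambda: {
        "A01": 1_000_000, "C01": 1_000_000, "A01_random": 200_000,
    })
    divergence_f: float = 0.2
    inbreeding: float = 0.95
    private_allele_fraction: float = 0.05
    homoeolog_artifact_rate: float = 0.1
    artifact_het_level: float = 0.8
    missing_rate: float = 0.1
    depth_mean: float = 10.0
    depth_dispersion: float = 5.0
    ld_block_len: int = 100_000
    ld_rho_within: float = 0.95
    transition_prob: float = 0.565
    n_genes_per_chrom: int = 60
    sv_n_deletions: int = 60
    sv_n_insertions: int = 20
    del_size_median: float = 88.0
    del_size_sigma: float = 1.0
    del_size_max: int = 15_420
    ins_size_range: tuple[int, int] = (50, 132)
    sv_carrier_freq_range: tuple[float, float] = (0.05, 0.5)
    caller_fp_rate: float = 0.1
    caller_fn_rate: float = 0.1
    caller_jitter_bp: int = 10
    emulate_pindel_only_insertions: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        for name in ("divergence_f", "inbreeding", "private_allele_fraction",
                     "homoeolog_artifact_rate", "artifact_het_level",
                     "missing_rate", "ld_rho_within", "caller_fp_rate",
                     "caller_fn_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if len(self.samples_per_group) != self.n_groups:
            raise ValueError("samples_per_group length must equal n_groups")
        if len(self.group_names) != self.n_groups:
            raise ValueError("group_names length must equal n_groups")


@dataclass
class SimTruth:
    """Ground truth recorded by the generators (fields filled as relevant)."""

    loci: list[Locus] = field(default_factory=list)
    ancestral_freq: np.ndarray | None = None
    group_freqs: dict[str, np.ndarray] = field(default_factory=dict)
    artifact_flags: np.ndarray | None = None
    private_flags: dict[str, np.ndarray] = field(default_factory=dict)
    # LD-haplotype truth
    block_ids: np.ndarray | None = None
    founder_indicators: np.ndarray | None = None
    haplotypes: np.ndarray | None = None
    expected_r2_within: float | None = None
    # SV truth
    sv_regions: list[SVRegion] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Reference + gene models
# ---------------------------------------------------------------------------

def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random non-stop, non-ATG-start-agnostic internal codons."""
    codons = []
    while len(codons) < n:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOP_CODONS:
            codons.append(c)
    return "".join(codons)


def _build_gene_layout(rng: np.random.Generator) -> list[tuple[str, str]]:
    """Transcription-order (kind, sequence) segments of one gene."""
    utr5 = "".join(rng.choice(_BASES, size=int(rng.integers(50, 150))))
    utr3 = "".join(rng.choice(_BASES, size=int(rng.integers(50, 150))))
    n_exons = int(rng.integers(2, 5))
    n_codons = int(rng.integers(60, 200))
    cds = "ATG" + _random_codons(rng, n_codons - 2) + str(rng.choice(_STOP_CODONS))
    # split the CDS into n_exons chunks (cut points need not respect codons)
    cuts = sorted(rng.choice(np.arange(10, len(cds) - 10), size=n_exons - 1,
                             replace=False)) if n_exons > 1 else []
    chunks = [cds[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(cds)])]
    segments: list[tuple[str, str]] = [("utr5", utr5)]
    for i, chunk in enumerate(chunks):
        if i > 0:
            ilen = int(rng.integers(60, 200))
            body = "".join(rng.choice(_BASES, size=ilen - 4))
            segments.append(("intron", "GT" + body + "AG"))
        segments.append(("cds", chunk))
    segments.append(("utr3", utr3))
    return segments


def simulate_reference(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random chromosomes with non-overlapping, strand-aware gene models.

    Every CDS starts with ATG, ends with a stop codon and is free of
    internal stops on the coding strand.
    """
    rng = np.random.default_rng(config.seed)
    for chrom, length in config.chromosome_lengths.items():
        if length < 10_000:
            raise ValueError(f"chromosome {chrom} shorter than 10 kb")
    sequences: dict[str, str] = {}
    models: list[GeneModel] = []
    for chrom, length in config.chromosome_lengths.items():
        seq = rng.choice(_BASES, size=length)
        occupied: list[tuple[int, int]] = []
        for gi in range(config.n_genes_per_chrom):
            strand = "+" if rng.random() < 0.5 else "-"
            layout = _build_gene_layout(rng)
            gene_len = sum(len(s) for _, s in layout)
            placed = None
            for _attempt in range(200):
                start = int(rng.integers(0, length - gene_len))
                if all(e <= start or s >= start + gene_len for s, e in occupied):
                    placed = start
                    break
            if placed is None:
                raise RuntimeError(
                    f"could not place gene {gi} on {chrom} without overlap; "
                    "lower n_genes_per_chrom"
                )
            occupied.append((placed, placed + gene_len))
            if strand == "-":
                genomic = [(k, _revcomp(s)) for k, s in reversed(layout)]
            else:
                genomic = layout
            tx = Transcript(transcript_id=f"{chrom}_g{gi}.1")
            pos = placed
            exon_start = None
            for kind, s in genomic:
                seg = (pos, pos + len(s))
                seq[seg[0]:seg[1]] = list(s)
                if kind == "intron":
                    if exon_start is not None:
                        tx.exons.append((exon_start, pos))
                        exon_start = None
                else:
                    if exon_start is None:
                        exon_start = pos
                    if kind == "cds":
                        tx.cds.append(seg)
                    elif kind == "utr5":
                        tx.utr5.append(seg)
                    else:
                        tx.utr3.append(seg)
                pos += len(s)
            if exon_start is not None:
                tx.exons.append((exon_start, pos))
            tx.sort()
            models.append(GeneModel(gene_id=f"{chrom}_g{gi}", chrom=chrom,
                                    strand=strand, transcripts=[tx]))
        sequences[chrom] = "".join(seq)
    return sequences, models


# ---------------------------------------------------------------------------
# Structured populations
# ---------------------------------------------------------------------------

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _draw_alt(rng: np.random.Generator, ref: str, transition_prob: float) -> str:
    """Alt allele with a transition-biased substitution spectrum."""
    if rng.random() < transition_prob:
        return _TRANSITION_PARTNER[ref]
    others = [b for b in "ACGT" if b != ref and b != _TRANSITION_PARTNER[ref]]
    return others[int(rng.integers(2))]


def _draw_loci(rng: np.random.Generator, config: SimConfig,
               reference: dict[str, str] | None = None) -> list[Locus]:
    loci = []
    for chrom, length in config.chromosome_lengths.items():
        pos = np.sort(rng.choice(np.arange(1, length + 1),
                                 size=config.n_loci_per_chrom, replace=False))
        for p in pos:
            if reference is not None:
                ref = reference[chrom][int(p) - 1]
            else:
                ref = str(rng.choice(_BASES))
            alt = _draw_alt(rng, ref, config.transition_prob)
            loci.append(Locus(chrom, int(p), ref, alt))
    loci.sort(key=lambda l: (l.chrom, l.pos))
    return loci


def simulate_populations(config: SimConfig,
                         reference: dict[str, str] | None = None,
                         ) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Genotypes for drifted sub-populations with private and artifact loci.

    Group allele frequencies follow the Balding–Nichols model: Beta with
    mean p0 ~ U(0.05, 0.95) and variance F * p0 * (1 - p0).  Private loci
    are polymorphic in exactly one group; artifact loci emit heterozygotes
    at ``artifact_het_level`` regardless of group frequency.  Missingness
    and negative-binomial depths are applied independently of genotype.
    """
    rng = np.random.default_rng(config.seed)
    loci = _draw_loci(rng, config, reference)
    n_loci = len(loci)
    groups = list(config.group_names)
    f = config.divergence_f

    p0 = rng.uniform(0.05, 0.95, size=n_loci)
    group_freqs: dict[str, np.ndarray] = {}
    for g in groups:
        if f > 0:
            a = p0 * (1 - f) / f
            b = (1 - p0) * (1 - f) / f
            group_freqs[g] = rng.beta(a, b)
        else:
            group_freqs[g] = p0.copy()

    # disjoint special loci: per-group private first, then artifact loci
    perm = rng.permutation(n_loci)
    cursor = 0
    private_flags = {g: np.zeros(n_loci, dtype=bool) for g in groups}
    n_private = int(round(config.private_allele_fraction * n_loci))
    for g in groups:
        chosen = perm[cursor:cursor + n_private]
        cursor += n_private
        private_flags[g][chosen] = True
        group_freqs[g][chosen] = rng.uniform(0.1, 0.4, size=len(chosen))
        for h in groups:
            if h != g:
                group_freqs[h][chosen] = 0.0
    n_artifact = int(round(config.homoeolog_artifact_rate * n_loci))
    artifact = np.zeros(n_loci, dtype=bool)
    artifact[perm[cursor:cursor + n_artifact]] = True

    samples: list[str] = []
    assignment: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for g, n_g in zip(groups, config.samples_per_group):
        p = group_freqs[g]
        for i in range(n_g):
            name = f"{g}_{i:03d}"
            samples.append(name)
            assignment[name] = g
            # selfing crop: varieties are near-homozygous inbred lines, so a
            # call is a doubled single allele draw with probability F_is and
            # a Hardy-Weinberg draw otherwise: P(het) = 2p(1-p)(1 - F_is)
            inbred = rng.random(n_loci) < config.inbreeding
            hom = (2 * rng.binomial(1, p)).astype(np.int8)
            hwe = rng.binomial(2, p).astype(np.int8)
            dosage = np.where(inbred, hom, hwe)
            if artifact.any():
                u = rng.random(n_loci)
                het = u < config.artifact_het_level
                hom_alt = u >= (1 + config.artifact_het_level) / 2
                forced = np.where(het, 1, np.where(hom_alt, 2, 0)).astype(np.int8)
                dosage = np.where(artifact, forced, dosage)
            rows.append(dosage)
    calls = np.stack(rows)

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)
    # negative binomial parameterised by mean m and dispersion k:
    # n=k, p=k/(k+m) so that Var = m + m^2/k
    k = config.depth_dispersion
    pnb = k / (k + config.depth_mean)
    depths = rng.negative_binomial(k, pnb, size=calls.shape).astype(np.int32)

    matrix = GenotypeMatrix(samples=samples, loci=loci, calls=calls, depths=depths)
    popmap = PopulationMap(assignment)
    truth = SimTruth(loci=loci, ancestral_freq=p0, group_freqs=group_freqs,
                     artifact_flags=artifact, private_flags=private_flags)
    return matrix, popmap, truth


# ---------------------------------------------------------------------------
# LD haplotype blocks
# ---------------------------------------------------------------------------

def simulate_ld_haplotypes(n_samples: int, n_loci: int, block_len: int,
                           rho_within: float, chrom_len: int, seed: int,
                           chrom: str = "A01", inbreeding: float = 1.0,
                           ) -> tuple[GenotypeMatrix, SimTruth]:
    """Dosages with block-local LD and independence across blocks.

    Each haplotype picks one of two complementary founder states per block
    (probability 1/2) and copies it with per-locus flip probability
    (1 - rho_within)/2, so a haplotype correlates with its block founder at
    rho_within; the expected inter-locus genotype r^2 within a block is
    rho_within**4 and 0 across blocks.  Two haplotypes per sample are
    summed to a dosage; with probability ``inbreeding`` (default 1: fully
    inbred lines, as in a selfing crop) the second haplotype copies the
    first at a locus, keeping observed heterozygosity below the stringent
    het cap used for LD-tier filtering.
    """
    if not 0 <= rho_within <= 1:
        raise ValueError("rho_within must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, chrom_len + 1), size=n_loci,
                             replace=False))
    block_ids = (pos - 1) // block_len
    uniq_blocks, block_col = np.unique(block_ids, return_inverse=True)
    eps = (1.0 - rho_within) / 2.0
    z = rng.random((2 * n_samples, len(uniq_blocks))) < 0.5
    flips = rng.random((2 * n_samples, n_loci)) < eps
    haplotypes = z[:, block_col] ^ flips
    if inbreeding > 0:
        copy = rng.random((n_samples, n_loci)) < inbreeding
        haplotypes[1::2] = np.where(copy, haplotypes[0::2], haplotypes[1::2])
    calls = (haplotypes[0::2].astype(np.int8) + haplotypes[1::2].astype(np.int8))
    depths = np.full(calls.shape, 10, dtype=np.int32)
    loci = []
    for p in pos:
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        loci.append(Locus(chrom, int(p), str(ref), str(alt)))
    matrix = GenotypeMatrix(samples=[f"S{i:03d}" for i in range(n_samples)],
                            loci=loci, calls=calls, depths=depths)
    truth = SimTruth(loci=loci, block_ids=block_ids,
                     founder_indicators=z[:, block_col],
                     haplotypes=haplotypes,
                     expected_r2_within=rho_within ** 4)
    return matrix, truth


# ---------------------------------------------------------------------------
# SV truth and pseudo-caller outputs
# ---------------------------------------------------------------------------

def _del_size(rng: np.random.Generator, config: SimConfig) -> int:
    size = int(round(rng.lognormal(math.log(config.del_size_median),
                                   config.del_size_sigma)))
    return int(np.clip(size, 50, config.del_size_max))


def simulate_sv_truth(config: SimConfig, samples: Sequence[str],
                      ) -> list[SVRegion]:
    """Non-overlapping truth deletions and insertion points with carriers."""
    rng = np.random.default_rng(config.seed + 7)
    chroms = list(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    regions: list[SVRegion] = []

    def place(span: int) -> tuple[str, int] | None:
        for _ in range(200):
            c = chroms[rng.choice(len(chroms), p=weights)]
            start = int(rng.integers(0, config.chromosome_lengths[c] - span))
            if all(e <= start or s >= start + span for s, e in occupied[c]):
                occupied[c].append((start, start + span))
                return c, start
        return None

    def carriers() -> frozenset[str]:
        freq = rng.uniform(*config.sv_carrier_freq_range)
        chosen = [s for s in samples if rng.random() < freq]
        if not chosen:
            chosen = [samples[int(rng.integers(len(samples)))]]
        return frozenset(chosen)

    for _ in range(config.sv_n_deletions):
        size = _del_size(rng, config)
        spot = place(size)
        if spot is None:
            continue
        c, start = spot
        regions.append(SVRegion(chrom=c, start=start, end=start + size,
                                sv_type="DEL", carriers=carriers(),
                                length_bp=size))
    for _ in range(config.sv_n_insertions):
        ins_len = int(rng.integers(config.ins_size_range[0],
                                   config.ins_size_range[1] + 1))
        spot = place(1)
        if spot is None:
            continue
        c, start = spot
        regions.append(SVRegion(chrom=c, start=start, end=start + 1,
                                sv_type="INS", carriers=carriers(),
                                length_bp=ins_len))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def simulate_sv_calls(truth_regions: Sequence[SVRegion], samples: Sequence[str],
                      fp_rate: float, fn_rate: float, jitter_bp: int, seed: int,
                      chromosome_lengths: dict[str, int] | None = None,
                      emulate_pindel_only_insertions: bool = True,
                      shared_fp_fraction: float = 0.5,
                      ) -> tuple[list[IntervalCall], list[IntervalCall]]:
    """Noisy per-sample calls from two pseudo-callers over a shared truth.

    Carriers emit one call per caller with probability (1 - fn_rate),
    endpoints jittered by +/- jitter_bp; false deletions are added per
    caller per sample at Poisson(fp_rate).  With probability
    ``shared_fp_fraction`` a false call is a caller-independent artifact
    (e.g. a homoeologous misalignment) that the other caller reports too,
    so two-caller consensus cannot remove it.  Insertions are emitted only
    by pseudo-caller B when the single-caller-insertions mode is on.
    """
    rng = np.random.default_rng(seed)
    calls_a: list[IntervalCall] = []
    calls_b: list[IntervalCall] = []

    def jitter(v: int) -> int:
        if jitter_bp == 0:
            return v
        return v + int(rng.integers(-jitter_bp, jitter_bp + 1))

    for region in truth_regions:
        for sample in sorted(region.carriers):
            for caller, sink in (("caller_a", calls_a), ("caller_b", calls_b)):
                if region.sv_type == "INS" and emulate_pindel_only_insertions \
                        and caller == "caller_a":
                    continue
                if rng.random() < fn_rate:
                    continue
                if region.sv_type == "DEL":
                    s, e = jitter(region.start), jitter(region.end)
                    if e <= s:
                        s, e = region.start, region.end
                    sink.append(IntervalCall(
                        sample=sample, chrom=region.chrom, start=s, end=e,
                        sv_type="DEL", caller=caller,
                        support=int(rng.integers(5, 30)), length=e - s))
                else:
                    s = jitter(region.start)
                    sink.append(IntervalCall(
                        sample=sample, chrom=region.chrom, start=s, end=s + 1,
                        sv_type="INS", caller=caller,
                        support=int(rng.integers(5, 30)),
                        length=region.length_bp))
    if fp_rate > 0 and chromosome_lengths:
        chroms = list(chromosome_lengths)
        sinks = {"caller_a": calls_a, "caller_b": calls_b}
        for caller, other in (("caller_a", "caller_b"),
                              ("caller_b", "caller_a")):
            for sample in samples:
                for _ in range(rng.poisson(fp_rate)):
                    c = chroms[int(rng.integers(len(chroms)))]
                    size = int(np.clip(round(rng.lognormal(math.log(88), 1.0)),
                                       50, 15_420))
                    start = int(rng.integers(0, chromosome_lengths[c] - size))
                    emit_to = [caller]
                    if rng.random() < shared_fp_fraction:
                        emit_to.append(other)
                    for lab in emit_to:
                        s, e = jitter(start), jitter(start + size)
                        if e <= s:
                            s, e = start, start + size
                        sinks[lab].append(IntervalCall(
                            sample=sample, chrom=c, start=s, end=e,
                            sv_type="DEL", caller=lab,
                            support=int(rng.integers(5, 30)), length=e - s))
    key = lambda c: (c.chrom, c.start, c.end, c.sample)
    return sorted(calls_a, key=key), sorted(calls_b, key=key)
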