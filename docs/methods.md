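# Methods

`germpop` re-implements, as a tested library, the genome-analysis workflow
used to characterise germplasm panels of an allotetraploid crop (canola,
*Brassica napus*, AACC): polyploid-aware SNP filtering, Nei-distance /
neighbor-joining / AMOVA diversity analysis, chromosome-wise LD decay,
SnpEff-style SNP effect annotation, and two-caller structural-variant
consensus. This note records the models, the defaults that matter, and the
choices made where the design was genuinely open.

## SNP filtering

Homoeologous regions of the A and C sub-genomes cross-align in short-read
data; a collapsed pair of homoeologs looks like a SNP whose carriers are
almost all heterozygous. Because canola varieties are inbred lines of a
selfing species, genuine SNPs show *low* heterozygosity, so a cap on the
per-locus heterozygous fraction is the discriminating rule. Three preset
tiers are provided:

| tier | min depth | max missing | min MAF | max het | MAF scope |
|---|---|---|---|---|---|
| discovery | 5 | 0.50 | 0.05 | 0.40 | any group |
| stringent | 5 | 0.50 | 0.05 | 0.10 | any group |
| LD | 5 | 0.40 | 0.10 | 0.10 | overall |

Interpretation choices:

- **Depth** is the mean read depth over non-missing calls at the locus
  (per-call masking below a depth threshold is additionally available at
  VCF read time). Depths of missing calls never enter the mean.
- **MAF scope** `any_group` passes a locus when at least one group reaches
  the threshold, matching a workflow in which MAF is "calculated
  separately" per panel after consolidating per-group discovery lists; a
  group with no non-missing calls at the locus abstains. `overall` pools
  all samples.
- **Heterozygosity** uses non-missing calls as its denominator.
- Rejection accounting attributes each dropped locus to the *first*
  failing rule in the fixed order depth → missing → MAF → het; the
  retained set itself is order-invariant (a locus must pass every enabled
  rule).
- `consolidate_lists` unions two discovery lists by (chrom, pos); a
  position present in both lists with conflicting alleles is dropped
  entirely and counted, never merged.
- A population-exclusive SNP has MAF ≥ the floor (default 0.05) in exactly
  one group and MAF = 0 in every other group, over non-missing calls.

## Nei distance, neighbor-joining, AMOVA

**Nei's standard distance (1972) between individuals.** A diploid genotype
is read as an allele-frequency vector, x = (1 − g/2, g/2) for dosage g.
With J_x = mean_l Σ_a x_a², J_y likewise, and J_xy = mean_l Σ_a x_a y_a
over the loci non-missing in *both* samples (pairwise-complete deletion),

    D(x, y) = −ln( J_xy / √(J_x · J_y) ).

Negative values from float noise are clamped to 0. A population-level
variant on pooled group frequencies is also provided.

**Neighbor joining** is the standard Saitou–Nei agglomeration: join the
pair minimising Q(i,j) = (n−2)·d(i,j) − r_i − r_j, with branch lengths from
the canonical formulas. Two determinism/validity choices: ties in Q break
to the lexicographically smallest pair of clade labels (a clade is labelled
by its smallest leaf), and a negative branch length is clamped to zero with
its deficit moved to the sibling branch, preserving leaf-to-leaf path
lengths. Output is an unrooted tree serialized as Newick with fixed-
precision branch lengths.

**AMOVA** is the one-level (among/within populations) partition on squared
pairwise distances:

    SSD_total  = (1/N) Σ_{i<j} d²(i,j)
    SSD_within = Σ_g (1/n_g) Σ_{i<j ∈ g} d²(i,j)
    σ²_w = SSD_within/(N−k),  σ²_a = (SSD_among/(k−1) − σ²_w)/n̄,
    n̄ = (N − Σ n_g²/N)/(k−1),  Φ_ST = σ²_a/(σ²_a + σ²_w)

with negative σ²_a clamped to 0. The permutation test relabels individuals
with group sizes fixed and uses the +1 correction,
p = (#{Φ_perm ≥ Φ_obs} + 1)/(n_perm + 1), so p is never 0 — a reported
"p = 0.000" corresponds here to p < 1/(n_perm+1).

*Distance fed to AMOVA.* Two options are selectable. The pipeline default
squares Nei's D. For parameter-recovery testing the package also provides
the classical squared Euclidean dosage distance, because only for that
metric do the variance components have closed forms in the group allele
frequencies: with Balding–Nichols drift F and inbreeding F_is,
σ²_a,l = Var_g(2p_g) and σ²_w,l = mean_g 2p_g(1−p_g)(1+F_is), giving a
truth Φ_ST ≈ 2F/(1+F·…) computable locus-by-locus from the recorded truth
frequencies. Nei's D is a log-identity measure; AMOVA on its square yields
a systematically larger Φ_ST (≈0.60 at F = 0.2 in our simulations), which
is not comparable against any frequency-derived truth value, so recovery
tests use the Euclidean mode.

## LD decay

r² is the squared Pearson correlation of unphased dosage vectors over
pairwise-complete samples (the genotype-count estimator of standard LD
tools); no EM haplotype estimation. Pairs with fewer than two complete
samples, or where either locus is monomorphic over the complete samples,
are skipped. Per chromosome, all pairs within a window (default 5 Mb) are
binned on an expanding graduated distance scale — 10 kb bins to 100 kb,
50 kb bins to 1 Mb, 250 kb bins to 5 Mb (configurable); the abrupt change
of bin width at a scheme boundary can produce a visible discontinuity in
the binned curve, which is a binning artifact, not signal. Bins are
half-open (lo, hi]; empty bins report count 0 and an undefined mean.

The decay distance at a threshold t scans non-empty bins in distance order
for the first adjacent pair crossing from ≥ t to < t and interpolates
linearly between bin midpoints; a first bin already below t reports 0
("below at origin"), and a curve that never crosses reports "not reached".
No smoothing is applied before threshold reading.

## Effect annotation

A point-query gene index maps each SNP to every overlapping transcript.
Categories: intergenic, intron, splice_acceptor/splice_donor (the first and
last 2 bp of an intron in transcription order — the canonical GT/AG
dinucleotides; width configurable), utr5/utr3 (strand-aware; inferred from
the CDS span when no explicit UTR feature covers the base), and the coding
set from codon substitution: the spliced CDS is assembled in genomic order,
reverse-complemented on minus-strand transcripts, the affected codon
rebuilt with the alt base and translated with the standard nuclear code.
Any change in the first codon is start_lost; ref-stop→non-stop is
stop_lost; non-stop→stop is stop_gained; otherwise synonymous or
non_synonymous by amino-acid identity.

One category per SNP is reported after severity resolution across
transcripts (start_lost = stop_gained = stop_lost > non_synonymous >
synonymous > splice > UTR > intron); the full per-transcript list is kept
in the detailed output. Transcripts whose concatenated CDS is not a
multiple of 3 are flagged `incomplete`: codon effects are still computed
where the codon is intact, and the untranslatable tail falls back to a
flagged synonymous call. A SNP whose stated reference allele disagrees with
the reference sequence is an error, not a silent skip.

The summary reports category counts and fractions of the genic total, the
genic/intergenic split, genes containing ≥ 1 SNP, and transitions (A↔G,
C↔T) versus transversions. The splice fraction is given against both the
genic and the intronic denominator, since either convention appears in the
literature.

## Structural-variant consensus

Deletions require both callers: within a sample, a caller-A deletion is
kept iff some caller-B deletion overlaps it with reciprocal overlap ≥ 0.5
(configurable; the matching is greedy by descending overlap, ties to the
leftmost pair, one partner per call), and the consensus interval is the
intersection of the matched pair — the conservative choice; a union mode
is a one-line change. Insertions come from the single caller that reports
them, filtered at support ≥ 5 like all calls.

Per-sample consensus calls are combined across samples by partitioning
each chromosome at every call endpoint and merging maximal runs with
identical carrier sets (the multi-intersect operation). Region filtering
keeps length ≥ 50 bp and carrier frequency ≥ 0.05 over *all* samples. An
insertion's length is the reported inserted-sequence length (its interval
is only an anchor point); a combined insertion region takes the median of
its carriers' reported lengths. Regions are annotated by feature overlap
as intergenic / intron / CDS / UTR / CDS+UTR. Summaries bucket chromosomes
not matching the `A##`/`C##` pattern as "Random scaffolds", and count
group-exclusive regions (all carriers from one group, no frequency floor —
deliberately weaker than the exclusive-SNP definition, which applies a MAF
floor).

## Synthetic data: what it emulates, and what it does not

The generator is the package's test substrate; every stochastic output is
a pure function of (config, seed).

- **Population structure**: Balding–Nichols island model. Ancestral
  frequency p0 ~ U(0.05, 0.95) per locus; each group's frequency is Beta
  with mean p0 and variance F·p0·(1−p0). Chosen because it produces
  AMOVA-recoverable structure with one interpretable parameter; F = 0.2 by
  default.
- **Inbreeding**: genotypes are a doubled single allele draw with
  probability F_is = 0.95, Hardy–Weinberg otherwise, so P(het) =
  2p(1−p)(1−F_is). Canola varieties are near-homozygous inbred lines of a
  selfing species; without this the stringent 10% het cap would reject
  most genuine polymorphisms, which inverts the filter's real-data
  behaviour.
- **Homoeolog artifacts** are modelled at the genotype level as loci
  forced to a heterozygote rate of 0.8 (a rate the source workflow never
  quantifies; exposed in config), not as duplicated reference segments —
  the pipeline consumes genotypes, and heterozygosity is the diagnostic.
- **Panel shape** defaults to two groups of 94 and 55 samples (a local
  spring panel vs a global diversity panel) on two 1 Mb chromosomes plus a
  200 kb unanchored scaffold, 400 loci each; depth is negative binomial
  with mean 10 (the targeted coverage) and dispersion 5; missingness 10%;
  the substitution spectrum is transition-biased at 0.565 so the expected
  Ts/Tv ratio is ≈ 1.3.
- **LD blocks**: loci fall in blocks of fixed physical length; each
  haplotype copies one of two complementary founder states per block with
  per-locus flip probability (1−ρ)/2, so haplotype–founder correlation is
  ρ, inter-locus allele correlation within a block is ρ² and expected
  genotype r² is ρ⁴; across blocks loci are independent. Mean r² at
  distance d decays like the probability two loci share a block, so the
  decay distance scales with block length. This reproduces block-local LD
  and its decay, not recombination-gradient fine structure.
- **Gene models**: non-overlapping genes on random strands with
  5'UTR–CDS(introns)–3'UTR structure, CDS a multiple of 3 starting ATG and
  ending in a stop with no internal stops, introns flanked by GT/AG. Gene
  density defaults to 60 genes per Mb chromosome (~15% genic), a
  realistic order for this genome.
- **SV truth and pseudo-callers**: non-overlapping deletion intervals with
  lognormal sizes (median 88 bp, clipped to 50–15,420 bp) and insertion
  points with lengths uniform in 50–132 bp, matching the reported ranges;
  carriers drawn per region at a frequency uniform in (0.05, 0.5). Callers
  miss a true call at fn_rate, jitter endpoints ±jitter_bp, and add false
  deletions at Poisson(fp_rate) per sample; *half* of false calls (by
  default) are caller-independent artifacts emitted by both callers —
  without that correlation, two-caller consensus removes every false
  positive and precision cannot degrade, which is unrealistic for
  artifacts rooted in the sample itself (e.g. homoeologous misalignment).
  Insertions are emitted only by pseudo-caller B in the default mode,
  mirroring a caller pair in which only one detects insertions.

A green test on this substrate establishes that the *implementation* of
each statistic and rule is correct against independent oracles and that
parameters of the stated generative world are recovered; it does not
establish read-level realism (no read simulation, no alignment, no
genotype-likelihood error model) nor selection/demography beyond the
island model.

## Numerical choices

- Missing dosage is the sentinel −1; every statistic's denominator is the
  non-missing (or pairwise-complete) count.
- Internal coordinates are 0-based half-open for all intervals; VCF
  positions stay 1-based; conversions happen only at I/O boundaries (GFF3
  1-based inclusive; SV TSVs declare their dialect in a `#dialect=`
  header line).
- Report-table mean distances round half-up to integer bp. Sub-genome and
  whole-genome rows are ratio-of-means (mean length / mean count), the
  only reading consistent with the published table they mirror.
- The first non-empty LD bins anchor threshold interpolation; bins are
  half-open on the right.
- NJ tie-breaks and the fixed rejection-attribution order exist purely for
  reproducibility; neither changes any retained set or tree metric.

## Known limitations

- AMOVA is one-level only (no region/hierarchy level) and assumes each
  sample belongs to exactly one group.
- The effect classifier implements the core category set, not a full
  effect ontology (no frameshift/indel effects — inputs are SNPs only).
- Pairwise r² is O(L·W) per chromosome (W = loci within the window); at
  full re-sequencing scale a specialized LD tool would be preferred.
- Half-missing genotypes ("0/.") are treated as missing and logged; no
  genotype-likelihood information is used.
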