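"""Two-tier, group-aware SNP filtering for allopolyploid genotype matrices.

Allotetraploid genomes (here the A/C sub-genome pair of *Brassica napus*)
inflate apparent heterozygosity wherever reads from homoeologous regions
co-align; a stringent heterozygosity cap is therefore the key polyploid-aware
rule alongside the usual depth / missingness / MAF thresholds.  Two preset
tiers mirror a discovery pass (het <= 0.40) and a stringent pass
(het <= 0.10), plus an LD-analysis tier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .formats_io import MISSING, GenotypeMatrix, Locus, PopulationMap

_SUBGENOME_RE = re.compile(r"(?:chr)?([AC])\d+$", re.IGNORECASE)


def subgenome_of(chrom: str) -> str:
    """Sub-genome bucket from the chromosome name: 'A', 'C' or 'U' (other/
    unanchored, e.g. random scaffolds)."""
    m = _SUBGENOME_RE.match(chrom)
    return m.group(1).upper() if m else "U"


@dataclass
class LocusStats:
    """Per-locus summary statistics, vectorised over all loci.

    Undefined quantities (e.g. MAF at a fully-missing locus) are NaN.
    """

    mean_depth: np.ndarray
    missing_fraction: np.ndarray
    het_fraction: np.ndarray
    maf_overall: np.ndarray
    maf_by_group: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_loci(self) -> int:
        return len(self.maf_overall)


@dataclass
class FilterConfig:
    """Thresholds for one filtering tier; ``None`` disables a rule.

    ``maf_scope='any_group'`` passes a locus when MAF meets the threshold in
    at least one group (groups with no non-missing call are excluded from
    the test); ``'overall'`` uses the pooled MAF.
    """

    min_depth: float | None = None
    max_missing: float | None = None
    min_maf: float | None = None
    max_het: float | None = None
    maf_scope: str = "overall"

    def __post_init__(self) -> None:
        if self.maf_scope not in ("overall", "any_group"):
            raise ValueError(f"maf_scope must be overall|any_group, got {self.maf_scope}")
        for name, hi in (("max_missing", 1), ("min_maf", 0.5), ("max_het", 1)):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= hi:
                raise ValueError(f"{name}={v} outside [0, {hi}]")


#: Discovery-pass thresholds: depth >= 5, missing <= 50%, MAF >= 5%, het <= 40%.
DISCOVERY_TIER = FilterConfig(min_depth=5, max_missing=0.5, min_maf=0.05,
                              max_het=0.4, maf_scope="any_group")
#: Stringent pass over the consolidated list: het cap tightened to 10%,
#: MAF still judged separately per group.
STRINGENT_TIER = FilterConfig(min_depth=5, max_missing=0.5, min_maf=0.05,
                              max_het=0.1, maf_scope="any_group")
#: LD-analysis tier: missing <= 40%, MAF >= 0.1 across all samples.
LD_TIER = FilterConfig(min_depth=5, max_missing=0.4, min_maf=0.1,
                       max_het=0.1, maf_scope="overall")


def _maf_from_calls(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(maf, n_nonmissing) per locus; maf is NaN where nothing is called."""
    nm = calls != MISSING
    n_nm = nm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(nm, calls, 0).sum(axis=0) / (2.0 * n_nm)
    maf = np.minimum(alt, 1.0 - alt)
    maf[n_nm == 0] = np.nan
    return maf, n_nm


def compute_locus_stats(matrix: GenotypeMatrix,
                        popmap: PopulationMap | None = None) -> LocusStats:
    """Depth, missingness, heterozygosity and MAF (overall and per group).

    All fractions use non-missing calls as the denominator; the depth of a
    MISSING call is excluded from the per-locus mean.
    """
    calls = matrix.calls
    nm = calls != MISSING
    n_nm = nm.sum(axis=0)
    n_samples = max(matrix.n_samples, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_depth = np.where(nm, matrix.depths, 0).sum(axis=0) / n_nm
        het = (calls == 1).sum(axis=0) / n_nm
    mean_depth = np.where(n_nm == 0, np.nan, mean_depth)
    het = np.where(n_nm == 0, np.nan, het)
    maf, _ = _maf_from_calls(calls)
    missing_fraction = 1.0 - n_nm / n_samples

    maf_by_group: dict[str, np.ndarray] = {}
    if popmap is not None:
        for group, idx in popmap.indices_by_group(matrix.samples).items():
            maf_by_group[group], _ = _maf_from_calls(calls[idx, :])
    return LocusStats(mean_depth=mean_depth, missing_fraction=missing_fraction,
                      het_fraction=het, maf_overall=maf, maf_by_group=maf_by_group)


_RULE_ORDER = ("depth", "missing", "maf", "het")


def _rule_pass(stats: LocusStats, config: FilterConfig) -> dict[str, np.ndarray]:
    """Boolean pass-vector per enabled rule; NaN statistics fail."""
    out: dict[str, np.ndarray] = {}
    with np.errstate(invalid="ignore"):
        if config.min_depth is not None:
            out["depth"] = stats.mean_depth >= config.min_depth
        if config.max_missing is not None:
            out["missing"] = stats.missing_fraction <= config.max_missing
        if config.min_maf is not None:
            if config.maf_scope == "overall" or not stats.maf_by_group:
                out["maf"] = stats.maf_overall >= config.min_maf
            else:
                per_group = np.stack([g >= config.min_maf
                                      for g in stats.maf_by_group.values()])
                out["maf"] = per_group.any(axis=0)
        if config.max_het is not None:
            out["het"] = stats.het_fraction <= config.max_het
    return out


def apply_filter(matrix: GenotypeMatrix, stats: LocusStats,
                 config: FilterConfig) -> tuple[np.ndarray, dict[str, int]]:
    """Retained locus indices plus first-fail rejection counts.

    A locus is retained iff it passes every enabled rule.  Each rejected
    locus is attributed to the first failing rule in the fixed order
    depth -> missing -> MAF -> heterozygosity; the retained set itself does
    not depend on that order.
    """
    passes = _rule_pass(stats, config)
    n = stats.n_loci
    retained = np.ones(n, dtype=bool)
    attributed = np.zeros(n, dtype=bool)
    counts = {rule: 0 for rule in _RULE_ORDER if rule in passes}
    for rule in _RULE_ORDER:
        if rule not in passes:
            continue
        fail_here = ~passes[rule] & ~attributed
        counts[rule] = int(fail_here.sum())
        attributed |= fail_here
        retained &= passes[rule]
    return np.flatnonzero(retained), counts


def consolidate_lists(list_a: Sequence[Locus],
                      list_b: Sequence[Locus]) -> tuple[list[Locus], int]:
    """Union of two sorted SNP lists keyed by (chrom, pos).

    Positions present in both lists with conflicting alleles are dropped
    entirely (returned conflict count); identical duplicates collapse to one.
    """
    by_pos: dict[tuple[str, int], Locus] = {}
    conflicts: set[tuple[str, int]] = set()
    for loc in list(list_a) + list(list_b):
        key = (loc.chrom, loc.pos)
        prev = by_pos.get(key)
        if prev is None:
            by_pos[key] = loc
        elif (prev.ref_allele, prev.alt_allele) != (loc.ref_allele, loc.alt_allele):
            conflicts.add(key)
    for key in conflicts:
        del by_pos[key]
    merged = [by_pos[k] for k in sorted(by_pos)]
    return merged, len(conflicts)


def exclusive_snps(matrix: GenotypeMatrix, popmap: PopulationMap,
                   min_maf: float = 0.05,
                   ) -> tuple[dict[str, np.ndarray], dict[str, dict[str, int]]]:
    """Group-exclusive loci and their per-sub-genome tallies.

    A locus is exclusive to group *g* iff its MAF >= ``min_maf`` within *g*
    and it is monomorphic (MAF == 0) in every other group, all computed over
    non-missing calls.  Returns ``(group -> locus index array,
    group -> {A/C/U -> count})``.
    """
    groups = popmap.groups
    if len(groups) < 2:
        raise ValueError("exclusive_snps requires at least 2 groups")
    idx_by_group = popmap.indices_by_group(matrix.samples)
    mafs = {g: _maf_from_calls(matrix.calls[idx_by_group[g], :])[0] for g in groups}
    sub = np.array([subgenome_of(l.chrom) for l in matrix.loci])

    exclusive: dict[str, np.ndarray] = {}
    tally: dict[str, dict[str, int]] = {}
    for g in groups:
        with np.errstate(invalid="ignore"):
            own = mafs[g] >= min_maf
            others_mono = np.ones(matrix.n_loci, dtype=bool)
            for h in groups:
                if h == g:
                    continue
                # a group with no calls at a locus cannot veto exclusivity
                others_mono &= np.where(np.isnan(mafs[h]), True, mafs[h] == 0)
        hits = np.flatnonzero(np.nan_to_num(own) * others_mono)
        exclusive[g] = hits
        tally[g] = {sg: int((sub[hits] == sg).sum()) for sg in ("A", "C", "U")}
    return exclusive, tally
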