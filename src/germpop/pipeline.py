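"""End-to-end orchestration: simulate -> filter -> diversity/AMOVA -> LD ->
annotate -> SV, plus the report-table builders (SNP density, exclusive SNPs,
SV distribution, effect summary).

Every report table is a schema-stable TSV whose header comments carry the
thresholds used, and a MANIFEST records completed stages so partial output
is auditable after a failure.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import effect_annotation as ea
from . import ld_decay as ld
from . import popgen_diversity as pd_div
from . import sv_consensus as svc
from . import synthetic_data as sim
from . import variant_filter as vf
from . import formats_io as fio

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def table1_stats(per_chrom_snp_counts: dict[str, int],
                 chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """SNP-density table: per-chromosome mean inter-SNP distance plus
    sub-genome and whole-genome mean rows.

    The mean distance per chromosome is round(length / count) (half-up);
    sub-genome and whole-genome rows are the ratio of the mean length to
    the mean SNP count over their chromosomes — not the mean of the
    per-chromosome ratios.  A zero count yields an NA distance.
    """
    chroms = sorted(per_chrom_snp_counts)
    rows = []
    for c in chroms:
        count = per_chrom_snp_counts[c]
        length = chrom_lengths[c]
        dist = _round_half_up(length / count) if count > 0 else None
        rows.append({"chromosome": c, "snps": count, "length_bp": length,
                     "mean_distance": dist})

    def mean_row(label: str, subset: list[str]) -> dict | None:
        if not subset:
            return None
        counts = [per_chrom_snp_counts[c] for c in subset]
        lengths = [chrom_lengths[c] for c in subset]
        mean_c = float(np.mean(counts))
        mean_l = float(np.mean(lengths))
        dist = _round_half_up(mean_l / mean_c) if mean_c > 0 else None
        return {"chromosome": label, "snps": _round_half_up(mean_c),
                "length_bp": _round_half_up(mean_l), "mean_distance": dist}

    a = [c for c in chroms if vf.subgenome_of(c) == "A"]
    cg = [c for c in chroms if vf.subgenome_of(c) == "C"]
    for label, subset in (("A genome mean", a), ("C genome mean", cg),
                          ("Whole genome mean", a + cg)):
        row = mean_row(label, subset)
        if row is not None:
            rows.append(row)
    return pd.DataFrame(rows)


def add_totals_row(df: pd.DataFrame, label: str = "Total",
                   label_column: str | None = None) -> pd.DataFrame:
    """Append a totals row summing every numeric column (Table 2/3 style)."""
    totals = {}
    for col in df.columns:
        if pd.api.types.is_numeric_dtype(df[col]):
            totals[col] = df[col].sum()
        else:
            totals[col] = ""
    if label_column is None:
        label_column = df.columns[0]
    totals[label_column] = label
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One config object driving every stage; seeds are mandatory wherever a
    stage is stochastic."""

    outdir: str = "germpop_out"
    seed: int = 1
    sim: dict = field(default_factory=dict)       # overrides for SimConfig
    amova_n_perm: int = 999
    ld_n_samples: int = 150
    ld_n_loci: int = 300
    ld_block_len: int = 100_000
    ld_rho_within: float = 0.95
    ld_chrom_len: int = 1_000_000
    ld_max_dist: int = 5_000_000
    ld_thresholds: tuple[float, ...] = (0.2, 0.1)
    sv_min_reciprocal_overlap: float = 0.5
    sv_min_length: int = 50
    sv_min_maf: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, provenance: str = "") -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic inputs and emit the report bundle.

    Returns a dict of in-memory artifacts keyed by stage.  Any stage
    failure raises :class:`PipelineError` naming the stage; the MANIFEST
    file lists the stages that completed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    artifacts: dict = {}
    manifest_path = out / "MANIFEST"

    def finish(stage: str) -> None:
        completed.append(stage)
        manifest_path.write_text("\n".join(completed) + "\n")

    def run_stage(stage: str, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            manifest_path.write_text("\n".join(completed) + "\n")
            raise PipelineError(stage, exc) from exc
        finish(stage)
        return result

    # --- simulate ---------------------------------------------------------
    def _simulate():
        sim_cfg = sim.SimConfig(seed=config.seed, **config.sim)
        reference, models = sim.simulate_reference(sim_cfg)
        matrix, popmap, truth = sim.simulate_populations(sim_cfg,
                                                         reference=reference)
        sv_truth = sim.simulate_sv_truth(sim_cfg, matrix.samples)
        calls_a, calls_b = sim.simulate_sv_calls(
            sv_truth, matrix.samples, sim_cfg.caller_fp_rate,
            sim_cfg.caller_fn_rate, sim_cfg.caller_jitter_bp,
            seed=sim_cfg.seed + 13,
            chromosome_lengths=sim_cfg.chromosome_lengths,
            emulate_pindel_only_insertions=sim_cfg.emulate_pindel_only_insertions,
        )
        fio.write_fasta(reference, out / "reference.fasta")
        fio.write_gff3(models, out / "genes.gff3")
        fio.write_vcf(matrix, out / "genotypes.vcf")
        fio.write_popmap(popmap, out / "popmap.tsv")
        fio.write_sv_calls(calls_a, out / "sv_caller_a.tsv")
        fio.write_sv_calls(calls_b, out / "sv_caller_b.tsv")
        return dict(sim_cfg=sim_cfg, reference=reference, models=models,
                    matrix=matrix, popmap=popmap, truth=truth,
                    sv_truth=sv_truth, calls_a=calls_a, calls_b=calls_b)

    artifacts["simulate"] = run_stage("simulate", _simulate)
    s = artifacts["simulate"]

    # --- filter -----------------------------------------------------------
    def _filter():
        matrix, popmap = s["matrix"], s["popmap"]
        # discovery tier per group, then list consolidation (the two-pass
        # discovery flow), then the stringent tier across all samples
        group_lists = []
        for g, idx in popmap.indices_by_group(matrix.samples).items():
            sub = matrix.subset_samples([matrix.samples[i] for i in idx])
            stats_g = vf.compute_locus_stats(sub)
            keep_g, _ = vf.apply_filter(sub, stats_g, vf.DISCOVERY_TIER)
            group_lists.append([sub.loci[i] for i in keep_g])
        prelim, conflicts = vf.consolidate_lists(*group_lists)
        keys = {(l.chrom, l.pos) for l in prelim}
        prelim_idx = [j for j, l in enumerate(matrix.loci)
                      if (l.chrom, l.pos) in keys]
        regeno = matrix.subset_loci(prelim_idx)
        stats = vf.compute_locus_stats(regeno, popmap)
        keep, rejections = vf.apply_filter(regeno, stats, vf.STRINGENT_TIER)
        filtered = regeno.subset_loci(keep)
        fio.write_vcf(filtered, out / "filtered.vcf")
        rej = pd.DataFrame(
            [{"rule": r, "rejected": n} for r, n in rejections.items()]
        )
        _write_tsv(rej, out / "filter_rejections.tsv",
                   provenance=f"stringent tier: {vf.STRINGENT_TIER}")
        excl, tally = vf.exclusive_snps(filtered, popmap, min_maf=0.05)
        tbl2 = pd.DataFrame(
            [{"sub_genome": sg,
              **{g: tally[g][sg] for g in popmap.groups}}
             for sg in ("A", "C", "U")]
        )
        tbl2 = add_totals_row(tbl2, label="Total")
        _write_tsv(tbl2, out / "table2_exclusive_snps.tsv",
                   provenance="exclusive SNP MAF floor 0.05")
        counts = pd.Series([l.chrom for l in filtered.loci]).value_counts()
        tbl1 = table1_stats(counts.to_dict(), s["sim_cfg"].chromosome_lengths)
        _write_tsv(tbl1, out / "table1_snp_density.tsv",
                   provenance=f"stringent tier: {vf.STRINGENT_TIER}")
        return dict(filtered=filtered, prelim_conflicts=conflicts,
                    rejections=rejections, exclusive=excl, tally=tally,
                    table1=tbl1, table2=tbl2)

    artifacts["filter"] = run_stage("filter", _filter)
    filtered = artifacts["filter"]["filtered"]

    # --- diversity --------------------------------------------------------
    def _diversity():
        dm = pd_div.nei_distance(filtered)
        tree = pd_div.neighbor_joining(dm)
        newick = fio.write_newick(tree)
        (out / "nj_tree.newick").write_text(newick + "\n")
        dist_df = pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels)
        dist_df.to_csv(out / "nei_distance.tsv", sep="\t")
        return dict(distance=dm, tree=tree, newick=newick)

    artifacts["diversity"] = run_stage("diversity", _diversity)

    # --- amova ------------------------------------------------------------
    def _amova():
        res = pd_div.amova(artifacts["diversity"]["distance"], s["popmap"],
                           n_perm=config.amova_n_perm, seed=config.seed + 101)
        df = pd.DataFrame([{
            "ssd_among": res.ssd_among, "ssd_within": res.ssd_within,
            "sigma2_among": res.sigma2_among, "sigma2_within": res.sigma2_within,
            "pct_among": res.pct_among, "pct_within": res.pct_within,
            "phi_st": res.phi_st, "p_value": res.p_value, "n_perm": res.n_perm,
        }])
        _write_tsv(df, out / "amova.tsv",
                   provenance=f"n_perm={config.amova_n_perm} seed={config.seed + 101}")
        return res

    artifacts["amova"] = run_stage("amova", _amova)

    # --- ld ---------------------------------------------------------------
    def _ld():
        ld_matrix, ld_truth = sim.simulate_ld_haplotypes(
            config.ld_n_samples, config.ld_n_loci, config.ld_block_len,
            config.ld_rho_within, config.ld_chrom_len, seed=config.seed + 29)
        stats = vf.compute_locus_stats(ld_matrix)
        keep, _ = vf.apply_filter(ld_matrix, stats, vf.LD_TIER)
        tier = ld_matrix.subset_loci(keep)
        pairs = ld.pairwise_r2(tier, "A01", max_dist=config.ld_max_dist)
        scheme = ld.expanding_scheme(config.ld_max_dist)
        binning = ld.bin_ld(pairs, scheme)
        bins_df = pd.DataFrame({
            "bin_lo": binning.edges[:-1], "bin_hi": binning.edges[1:],
            "midpoint": binning.midpoints, "n_pairs": binning.counts,
            "mean_r2": binning.mean_r2,
        })
        _write_tsv(bins_df, out / "ld_bins.tsv",
                   provenance=f"LD tier: {vf.LD_TIER}; max_dist={config.ld_max_dist}")
        decays = []
        for thr in config.ld_thresholds:
            dist, status = ld.decay_distance(binning, thr)
            decays.append({"r2_threshold": thr, "decay_distance_bp": dist,
                           "status": status})
        _write_tsv(pd.DataFrame(decays), out / "ld_decay.tsv")
        return dict(matrix=ld_matrix, truth=ld_truth, binning=binning,
                    decays=decays)

    artifacts["ld"] = run_stage("ld", _ld)

    # --- annotate ---------------------------------------------------------
    def _annotate():
        index = ea.build_gene_index(s["models"])
        effects, summary = ea.annotate_all(filtered.loci, index, s["reference"])
        _write_tsv(ea.effects_table(effects), out / "snp_effects.tsv")
        rows = [{"metric": "n_snps", "value": summary["n_snps"]},
                {"metric": "n_genic", "value": summary["n_genic"]},
                {"metric": "n_intergenic", "value": summary["n_intergenic"]},
                {"metric": "pct_intergenic", "value": summary["pct_intergenic"]},
                {"metric": "genes_with_snp", "value": summary["genes_with_snp"]},
                {"metric": "transitions", "value": summary["transitions"]},
                {"metric": "transversions", "value": summary["transversions"]},
                {"metric": "ts_tv_ratio",
                 "value": round(summary["ts_tv_ratio"], 4)}]
        for cat, n in summary["counts"].items():
            rows.append({"metric": f"count_{cat}", "value": n})
        for cat, p in summary["pct_of_genic"].items():
            rows.append({"metric": f"pct_genic_{cat}", "value": p})
        _write_tsv(pd.DataFrame(rows), out / "effect_summary.tsv")
        return dict(index=index, effects=effects, summary=summary)

    artifacts["annotate"] = run_stage("annotate", _annotate)

    # --- sv ---------------------------------------------------------------
    def _sv():
        n_samples = s["matrix"].n_samples
        cons_del = svc.consensus_deletions(
            s["calls_a"], s["calls_b"],
            min_reciprocal_overlap=config.sv_min_reciprocal_overlap)
        ins = svc.insertions_pass_through(s["calls_b"])
        del_regions = svc.filter_sv_regions(
            svc.combine_regions(cons_del), n_samples,
            min_length=config.sv_min_length, min_maf=config.sv_min_maf)
        ins_regions = svc.filter_sv_regions(
            svc.combine_regions(ins), n_samples,
            min_length=config.sv_min_length, min_maf=config.sv_min_maf) \
            if ins else []
        annotated, summary = svc.annotate_svs(
            {"DEL": del_regions, "INS": ins_regions},
            artifacts["annotate"]["index"], s["popmap"])
        tbl3 = summary.per_chromosome.reset_index()
        tbl3 = add_totals_row(tbl3, label="Total")
        _write_tsv(tbl3, out / "table3_sv_distribution.tsv",
                   provenance=(f"reciprocal_overlap>={config.sv_min_reciprocal_overlap} "
                               f"min_length={config.sv_min_length} "
                               f"min_maf={config.sv_min_maf}"))
        region_rows = [{
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "sv_type": r.sv_type, "length_bp": r.length_bp,
            "n_carriers": len(r.carriers), "category": r.category,
            "genes": ",".join(r.genes) or ".",
            "carriers": ",".join(sorted(r.carriers)),
        } for svt in ("DEL", "INS") for r in annotated.get(svt, [])]
        _write_tsv(pd.DataFrame(region_rows), out / "sv_regions.tsv")
        return dict(annotated=annotated, summary=summary, table3=tbl3)

    artifacts["sv"] = run_stage("sv", _sv)

    # --- report manifest --------------------------------------------------
    (out / "run_config.json").write_text(
        json.dumps(asdict(config), indent=2, default=str) + "\n")
    return artifacts
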