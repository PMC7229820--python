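"""End-to-end driver: load a data bundle, run every stage, write the report.

Stage order mirrors the analysis narrative: differential expression ->
9-square dependent-gene selection -> trajectory scaling -> peak Venn
overlaps -> promoter targets -> reduced peaks -> binned correlation ->
metagene profiles -> TET1-bound stratification -> DE x binding-loss
association -> over-representation analysis. Each stage writes its own TSV
so partial reruns and audits are cheap; the summary lists every headline
count and percentage. The whole run is deterministic given the inputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as nio
from .chromatin import (
    binned_correlation,
    chi_squared_association,
    identify_reduced_peaks,
    intersect_peaks,
    metagene_profile,
    pct,
    promoter_targets,
    stratify_expression_by_binding,
    target_gene_venn,
)
from .core import ExpressionMatrix, GeneModel, PeakSet, PipelineConfig, SignalTrack
from .enrichment import GeneSetCollection, ora_hypergeometric
from .expression import (
    classify_nine_square,
    differential_expression,
    fpkm_to_tpm,
    scale_trajectories,
    select_dependent_genes,
    top_differential,
)

log = logging.getLogger("nonotet.pipeline")

PEAK_FILES = {
    "TET1_WT": "peaks_tet1_wt.bed",
    "TET1_KO": "peaks_tet1_ko.bed",
    "NONO_WT": "peaks_nono_wt.bed",
    "hmC_WT": "peaks_hmc_wt.bed",
    "hmC_KO": "peaks_hmc_ko.bed",
}
TRACK_FILES = {k: f"track_{k.lower()}.bedgraph" for k in PEAK_FILES}


@dataclass
class Bundle:
    """Everything one analysis run consumes, as loaded from a directory."""

    genes: list[GeneModel]
    expression: ExpressionMatrix
    peaks: dict[str, PeakSet]
    tracks: dict[str, SignalTrack]
    chrom_sizes: dict[str, int]
    gene_sets: dict[str, set[str]] = field(default_factory=dict)


def load_bundle(input_dir, bin_size: int) -> Bundle:
    """Load the simulator (or user-supplied, same layout) directory.

    ``bin_size`` is the quantification bin for the in-memory tracks; the
    pipeline coarsens them later for the genome-wide correlation.
    """
    d = Path(input_dir)
    for required in ["genes.bed", "expression_fpkm.tsv", "chrom.sizes"]:
        if not (d / required).exists():
            raise FileNotFoundError(f"missing input file: {d / required}")
    chrom_sizes = nio.read_chrom_sizes(d / "chrom.sizes")
    genes = nio.read_bed(d / "genes.bed", kind="genes")
    expression = nio.read_expression_tsv(d / "expression_fpkm.tsv")
    peaks, tracks = {}, {}
    for key, fname in PEAK_FILES.items():
        path = d / fname
        if not path.exists():
            raise FileNotFoundError(f"missing input file: {path}")
        ps = nio.read_bed(path, kind="peaks")
        ps.name = key
        peaks[key] = ps
    for key, fname in TRACK_FILES.items():
        path = d / fname
        if not path.exists():
            raise FileNotFoundError(f"missing input file: {path}")
        tracks[key] = nio.read_bedgraph(path, bin_size, chrom_sizes)
    gene_sets: dict[str, set[str]] = {}
    gs_path = d / "gene_sets.tsv"
    if gs_path.exists():
        df = pd.read_csv(gs_path, sep="\t")
        for name, grp in df.groupby("set_name"):
            gene_sets[name] = set(grp["gene_id"])
    return Bundle(genes, expression, peaks, tracks, chrom_sizes, gene_sets)


def score_recovery(predicted: set[str], truth: set[str]) -> dict[str, float]:
    """Sensitivity (recall), precision and F1 of a recovered gene set."""
    tp = len(predicted & truth)
    sens = tp / len(truth) if truth else float("nan")
    prec = tp / len(predicted) if predicted else 0.0
    f1 = (2 * sens * prec / (sens + prec)) if (sens + prec) > 0 else 0.0
    return {"sensitivity": sens, "precision": prec, "f1": f1}


def run_pipeline(cfg: PipelineConfig, input_dir, out_dir) -> dict:
    """Execute every stage on a bundle directory; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_bundle(input_dir, cfg.quant_bin_bp)
    expr = bundle.expression
    genes = bundle.genes
    summary: dict = {"config": cfg.__dict__.copy(), "stages": []}

    def stage(name: str) -> None:
        summary["stages"].append(name)
        log.info("stage %s", name)

    # 1. TPM normalization (recorded alongside; DE runs on FPKM means)
    stage("tpm")
    tpm = fpkm_to_tpm(expr)
    nio.write_expression_tsv(tpm, out / "expression_tpm.tsv")

    # 2. differential expression: day 12 vs day 0 within each genotype
    stage("de")
    de = {}
    for g in ("WT", "KO", "KO_WT"):
        de[g] = differential_expression(
            expr, expr.sample_ids(g, 0), expr.sample_ids(g, 12), cfg)
        de[g].to_csv(out / f"de_{g}_d12_vs_d0.tsv", sep="\t",
                     index_label="gene_id")

    # 3. nine-square stage-1 grid (WT x, KO y)
    stage("ninesquare")
    grid1 = classify_nine_square(de["WT"]["log2fc"], de["KO"]["log2fc"],
                                 cfg.cutoff_log2, "WT_d12_vs_d0",
                                 "KO_d12_vs_d0")
    grid1.labels.rename("group").to_csv(out / "ninesquare_stage1.tsv", sep="\t",
                                        index_label="gene_id")

    # 4. rescue-validated dependent genes
    stage("dependent_genes")
    dep = select_dependent_genes(de["WT"], de["KO"], de["KO_WT"], cfg)
    with open(out / "dependent_genes.tsv", "w") as fh:
        fh.write("gene_id\tdirection\n")
        for gid in sorted(dep.up_dependent):
            fh.write(f"{gid}\tup\n")
        for gid in sorted(dep.down_dependent):
            fh.write(f"{gid}\tdown\n")

    # 5. scaled trajectories and top differential genes of the dependent sets
    stage("trajectories")
    focus = sorted(dep.up_dependent | dep.down_dependent)
    if focus:
        traj = scale_trajectories(expr, focus)
        traj.scaled.to_csv(out / "trajectories_scaled.tsv", sep="\t")
    top_up = top_differential(de["KO_WT"].loc[sorted(dep.up_dependent)],
                              min(50, len(dep.up_dependent)))
    pd.Series(top_up, name="gene_id").to_csv(out / "top_dependent_up.tsv",
                                             sep="\t", index=False)

    # 6. peak Venn overlaps
    stage("overlaps")
    ov_tet1 = intersect_peaks(bundle.peaks["TET1_WT"], bundle.peaks["TET1_KO"])
    ov_nono = intersect_peaks(bundle.peaks["NONO_WT"], bundle.peaks["TET1_WT"])
    with open(out / "overlaps.tsv", "w") as fh:
        fh.write("comparison\tn_a\tn_b\tn_overlap_a\tn_overlap_b\tpct_a\n")
        for label, ov in (("TET1_WT_vs_TET1_KO", ov_tet1),
                          ("NONO_WT_vs_TET1_WT", ov_nono)):
            fh.write(f"{label}\t{ov.n_a}\t{ov.n_b}\t{ov.n_overlap_a}"
                     f"\t{ov.n_overlap_b}\t{ov.pct_a_overlapping}\n")

    # 7. promoter target genes and their Venn
    stage("promoter_targets")
    assign_wt = promoter_targets(bundle.peaks["TET1_WT"], genes,
                                 cfg.promoter_flank_bp)
    assign_ko = promoter_targets(bundle.peaks["TET1_KO"], genes,
                                 cfg.promoter_flank_bp)
    common, wt_only, ko_only = target_gene_venn(assign_wt, assign_ko)
    with open(out / "target_genes.tsv", "w") as fh:
        fh.write("gene_id\tgroup\n")
        for gid in sorted(common):
            fh.write(f"{gid}\tcommon\n")
        for gid in sorted(wt_only):
            fh.write(f"{gid}\tWT_specific\n")
        for gid in sorted(ko_only):
            fh.write(f"{gid}\tKO_specific\n")

    # 8. reduced TET1 peaks (occupancy ratio on the binned tracks)
    stage("reduced_peaks")
    red = identify_reduced_peaks(bundle.peaks["TET1_WT"],
                                 bundle.tracks["TET1_WT"],
                                 bundle.tracks["TET1_KO"], cfg)
    with open(out / "reduced_peaks.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tname\tlog2_ratio\treduced\n")
        for iv, lr, fl in zip(red.reference, red.log2_ratio, red.flagged):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}"
                     f"\t{lr:.4f}\t{int(fl)}\n")
    reduced_target_genes = {
        iv.name for iv, fl in zip(red.reference, red.flagged) if fl and iv.name
    } & {g.gene_id for g in genes}

    # 9. NONO-TET1 genome-binned correlation (coarse non-overlapping bins)
    stage("correlation")
    r, bins = binned_correlation(
        bundle.tracks["NONO_WT"].rebin(cfg.bin_size_bp),
        bundle.tracks["TET1_WT"].rebin(cfg.bin_size_bp))
    bins.to_csv(out / "binned_signal.tsv", sep="\t", index=False)

    # 10. metagene profiles of 5hmC at reduced-target promoters / bodies
    stage("metagene")
    gmap = {g.gene_id: g for g in genes}
    profile_genes = [gmap[g] for g in sorted(reduced_target_genes)] or genes
    step = max(1, cfg.metagene_flank_bp // 10)
    for cond in ("hmC_WT", "hmC_KO"):
        for mode in ("tss", "genebody"):
            prof = metagene_profile(bundle.tracks[cond], profile_genes, mode,
                                    cfg, step_bp=step if mode == "tss" else None)
            pd.DataFrame({"position": prof.positions,
                          "mean_signal": prof.mean_signal}).to_csv(
                out / f"metagene_{cond.lower()}_{mode}.tsv", sep="\t",
                index=False)

    # 11. TET1-bound stratification at the naive stage
    stage("stratification")
    strat = stratify_expression_by_binding(
        genes, assign_wt,
        {"tet1_wt": bundle.tracks["TET1_WT"], "tet1_ko": bundle.tracks["TET1_KO"],
         "hmc_wt": bundle.tracks["hmC_WT"], "hmc_ko": bundle.tracks["hmC_KO"]},
        expr, cfg)
    strat.group_means.to_csv(out / "stratification.tsv", sep="\t")

    # 12. naive-stage DE and its association with binding loss
    stage("association")
    de_naive = differential_expression(
        expr, expr.sample_ids("WT", 0), expr.sample_ids("KO", 0), cfg)
    de_naive.to_csv(out / "de_KO_vs_WT_d0.tsv", sep="\t", index_label="gene_id")
    de_genes = set(de_naive.index[de_naive["status"] != "ns"])
    universe = {g.gene_id for g in genes}
    assoc = chi_squared_association(de_genes, reduced_target_genes, universe)
    with open(out / "association.tsv", "w") as fh:
        fh.write("de_and_reduced\tde_only\treduced_only\tneither\tchi2\tp_value\n")
        t = assoc.table
        fh.write(f"{int(t[0,0])}\t{int(t[0,1])}\t{int(t[1,0])}\t{int(t[1,1])}"
                 f"\t{assoc.chi2:.4f}\t{assoc.p_value:.4g}\n")

    # 13. over-representation of the dependent-up set
    stage("ora")
    ora = pd.DataFrame()
    if bundle.gene_sets:
        coll = GeneSetCollection(bundle.gene_sets, universe)
        ora = ora_hypergeometric(dep.up_dependent & universe, coll)
        ora.to_csv(out / "ora_up_dependent.tsv", sep="\t", index=False)

    summary.update({
        "n_genes": len(genes),
        "n_stage1_up": len(dep.stage1_up),
        "n_stage1_down": len(dep.stage1_down),
        "n_up_dependent": len(dep.up_dependent),
        "n_down_dependent": len(dep.down_dependent),
        "pct_up_dependent_of_stage1": pct(len(dep.up_dependent),
                                          len(dep.stage1_up)),
        "pct_down_dependent_of_stage1": pct(len(dep.down_dependent),
                                            len(dep.stage1_down)),
        "n_tet1_peaks_wt": ov_tet1.n_a,
        "n_tet1_peaks_ko": ov_tet1.n_b,
        "n_nono_peaks": ov_nono.n_a,
        "n_nono_cobound_tet1": ov_nono.n_overlap_a,
        "pct_nono_cobound_tet1": ov_nono.pct_a_overlapping,
        "n_target_genes_common": len(common),
        "n_target_genes_wt_specific": len(wt_only),
        "n_target_genes_ko_specific": len(ko_only),
        "n_reduced_peaks": int(red.flagged.sum()),
        "fraction_reduced_peaks": red.fraction_reduced,
        "pearson_r_nono_tet1_binned": r,
        "n_de_naive": len(de_genes),
        "n_de_naive_up": int((de_naive["status"] == "up").sum()),
        "n_de_naive_down": int((de_naive["status"] == "down").sum()),
        "chi2": assoc.chi2,
        "chi2_p_value": assoc.p_value,
        "strat_log2_binding_bound": float(
            strat.group_means.loc["TET1_bound", "log2_binding"]),
        "strat_log2_hmc_bound": float(
            strat.group_means.loc["TET1_bound", "log2_hmc"]),
        "strat_log2_expression_bound": float(
            strat.group_means.loc["TET1_bound", "log2_expression"]),
    })
    write_report(summary, out)
    return summary


def write_report(summary: dict, out_dir) -> None:
    """Write summary.json plus a human-readable text report.

    Percentages are printed as round-half-away-from-zero integers next to
    the raw fractions; every number is traceable to a stage TSV.
    """
    out = Path(out_dir)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    lines = ["nonotet pipeline summary", "=" * 24, ""]
    lines.append(f"stages run: {', '.join(summary['stages'])}")
    lines.append("")
    s = summary
    lines += [
        f"genes analysed: {s['n_genes']}",
        f"stage-1 up (F u I): {s['n_stage1_up']}; "
        f"rescue-validated up (F' u I'): {s['n_up_dependent']} "
        f"({s['pct_up_dependent_of_stage1']}%)",
        f"stage-1 down (A u D): {s['n_stage1_down']}; "
        f"rescue-validated down (A'' u D''): {s['n_down_dependent']} "
        f"({s['pct_down_dependent_of_stage1']}%)",
        f"TET1 peaks WT/KO: {s['n_tet1_peaks_wt']}/{s['n_tet1_peaks_ko']}",
        f"NONO peaks co-bound with TET1: {s['n_nono_cobound_tet1']}/"
        f"{s['n_nono_peaks']} ({s['pct_nono_cobound_tet1']}%)",
        f"promoter target genes common/WT-only/KO-only: "
        f"{s['n_target_genes_common']}/{s['n_target_genes_wt_specific']}/"
        f"{s['n_target_genes_ko_specific']}",
        f"reduced TET1 peaks: {s['n_reduced_peaks']} "
        f"(fraction {s['fraction_reduced_peaks']:.3f})",
        f"NONO-TET1 binned Pearson r: {s['pearson_r_nono_tet1_binned']:.3f}",
        f"naive-stage DE genes (up/down): {s['n_de_naive_up']}/"
        f"{s['n_de_naive_down']}",
        f"DE x reduced-binding chi2: {s['chi2']:.2f} "
        f"(p = {s['chi2_p_value']:.3g})",
    ]
    with open(out / "summary.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")
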