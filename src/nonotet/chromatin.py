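"""Interval algebra and signal analytics linking chromatin peaks to genes.

Covers the occupancy side of the analysis: peak-set Venn overlaps, promoter
target-gene assignment, identification of peaks with reduced occupancy in
the knockout, genome-wide binned Pearson correlation of two tracks, TSS /
gene-body metagene profiles, stratification of binding / 5hmC / expression
changes by promoter TET1 status, and the chi-squared association between
differential expression and binding loss.
"""
from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ExpressionMatrix,
    GeneModel,
    Interval,
    PeakSet,
    PipelineConfig,
    SignalTrack,
    ValidationError,
)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (85.5 -> 86, -0.5 -> -1)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def pct(k: int, n: int) -> int:
    """Integer percentage as printed in reports (half away from zero)."""
    if n == 0:
        return 0
    return round_half_away(100.0 * k / n)


@dataclass
class OverlapResult:
    """Venn counts between two peak sets (>=1 bp shared, same chrom)."""

    n_a: int
    n_b: int
    n_overlap_a: int  # peaks of A overlapping >=1 peak of B
    n_overlap_b: int
    a_overlapping: list[Interval] = field(repr=False, default_factory=list)
    a_only: list[Interval] = field(repr=False, default_factory=list)

    @property
    def n_a_only(self) -> int:
        return self.n_a - self.n_overlap_a

    @property
    def n_b_only(self) -> int:
        return self.n_b - self.n_overlap_b

    @property
    def pct_a_overlapping(self) -> int:
        return pct(self.n_overlap_a, self.n_a)


def _check_sorted(ps: PeakSet) -> None:
    key = [(iv.chrom, iv.start) for iv in ps.intervals]
    if key != sorted(key):
        raise ValidationError(f"peak set {ps.name!r} is not sorted")


def _count_overlapping(a: list[Interval], b: list[Interval]) -> np.ndarray:
    """Boolean mask over ``a``: overlaps >=1 interval of ``b`` (same chrom).

    Linear merge-sweep over the two sorted lists; handles nested/contained
    intervals by tracking the running max end on the b side.
    """
    mask = np.zeros(len(a), dtype=bool)
    by_chrom_b: dict[str, list[Interval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    by_chrom_a: dict[str, list[tuple[int, Interval]]] = {}
    for i, iv in enumerate(a):
        by_chrom_a.setdefault(iv.chrom, []).append((i, iv))
    for chrom, avs in by_chrom_a.items():
        bvs = by_chrom_b.get(chrom, [])
        starts = [iv.start for iv in bvs]
        # prefix running max of ends lets a binary probe answer
        # "does any b starting before a.end reach past a.start?"
        maxend = []
        cur = -1
        for iv in bvs:
            cur = max(cur, iv.end)
            maxend.append(cur)
        for i, iv in avs:
            j = bisect.bisect_left(starts, iv.end)  # b's with start < a.end
            if j > 0 and maxend[j - 1] > iv.start:
                mask[i] = True
    return mask


def intersect_peaks(a: PeakSet, b: PeakSet) -> OverlapResult:
    """Count peaks of each set overlapping the other (the Venn numbers)."""
    _check_sorted(a)
    _check_sorted(b)
    mask_a = _count_overlapping(a.intervals, b.intervals)
    mask_b = _count_overlapping(b.intervals, a.intervals)
    return OverlapResult(
        n_a=len(a), n_b=len(b),
        n_overlap_a=int(mask_a.sum()), n_overlap_b=int(mask_b.sum()),
        a_overlapping=[iv for iv, m in zip(a.intervals, mask_a) if m],
        a_only=[iv for iv, m in zip(a.intervals, mask_a) if not m],
    )


@dataclass
class PromoterAssignment:
    """Peaks assigned to gene promoter windows [tss - flank, tss + flank)."""

    flank: int
    assignments: dict[str, list[int]]  # gene_id -> indices into the peak set

    @property
    def target_genes(self) -> set[str]:
        return {g for g, idx in self.assignments.items() if idx}


def promoter_targets(peaks: PeakSet, genes: list[GeneModel],
                     flank: int) -> PromoterAssignment:
    """Assign peaks to genes whose promoter window they intersect.

    The window is strand-aware via the TSS (end - 1 on minus-strand genes)
    and clipped at coordinate 0.
    """
    if flank <= 0:
        raise ValidationError("flank must be positive")
    by_chrom: dict[str, list[tuple[int, Interval]]] = {}
    for i, iv in enumerate(peaks.intervals):
        by_chrom.setdefault(iv.chrom, []).append((i, iv))
    starts = {c: [iv.start for _i, iv in lst] for c, lst in by_chrom.items()}
    assignments: dict[str, list[int]] = {}
    for g in genes:
        lo, hi = g.promoter(flank)
        hits: list[int] = []
        lst = by_chrom.get(g.chrom, [])
        if lst:
            j = bisect.bisect_left(starts[g.chrom], hi)
            for i, iv in lst[:j]:
                if iv.end > lo:
                    hits.append(i)
        assignments[g.gene_id] = hits
    return PromoterAssignment(flank, assignments)


def target_gene_venn(assign_a: PromoterAssignment,
                     assign_b: PromoterAssignment) -> tuple[set, set, set]:
    """(common, a_specific, b_specific) partition of the targeted genes."""
    ta, tb = assign_a.target_genes, assign_b.target_genes
    return ta & tb, ta - tb, tb - ta


@dataclass
class ReducedPeakSet:
    """Peaks whose occupancy drops below the cutoff in the knockout."""

    reference: PeakSet
    log2_ratio: np.ndarray       # log2((KO + pc) / (WT + pc)) per peak
    flagged: np.ndarray          # bool per peak
    cutoff_log2: float

    @property
    def reduced(self) -> PeakSet:
        ivs = [iv for iv, f in zip(self.reference.intervals, self.flagged) if f]
        return PeakSet(f"{self.reference.name}_reduced", ivs)

    @property
    def fraction_reduced(self) -> float:
        return float(self.flagged.mean()) if len(self.flagged) else 0.0


def identify_reduced_peaks(peaks_ref: PeakSet, track_wt: SignalTrack,
                           track_ko: SignalTrack,
                           cfg: PipelineConfig) -> ReducedPeakSet:
    """Flag peaks with log2((KO + pc)/(WT + pc)) <= reduced_log2_cutoff.

    Per-condition signal is the length-weighted mean track value over the
    peak span.
    """
    if not track_wt.same_binning(track_ko):
        raise ValidationError("WT and KO tracks have different binning")
    pc = cfg.pseudocount
    ratios = np.empty(len(peaks_ref))
    for i, iv in enumerate(peaks_ref):
        wt = track_wt.mean_over(iv.chrom, iv.start, iv.end)
        ko = track_ko.mean_over(iv.chrom, iv.start, iv.end)
        ratios[i] = math.log2((ko + pc) / (wt + pc))
    flagged = ratios <= cfg.reduced_log2_cutoff
    return ReducedPeakSet(peaks_ref, ratios, flagged, cfg.reduced_log2_cutoff)


def binned_correlation(track_a: SignalTrack,
                       track_b: SignalTrack) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of two tracks over all genome bins.

    Zero-signal bins are included, mirroring a bedtools-style binned read
    count workflow. Returns (r, table of per-bin paired values).
    """
    if not track_a.same_binning(track_b):
        raise ValidationError("tracks have different binning")
    rows = []
    for chrom in sorted(track_a.chrom_sizes):
        va, vb = track_a.values[chrom], track_b.values[chrom]
        for b, (x, y) in enumerate(zip(va, vb)):
            rows.append((chrom, b * track_a.bin_size, x, y))
    table = pd.DataFrame(rows, columns=["chrom", "bin_start", "a", "b"])
    if len(table) < 3:
        raise ValidationError("need >=3 bins for a correlation")
    if table["a"].std() == 0 or table["b"].std() == 0:
        raise ValidationError("constant track: correlation undefined")
    r, _p = stats.pearsonr(table["a"], table["b"])
    return float(r), table


@dataclass
class MetageneProfile:
    """Average signal around TSSs or along scaled gene bodies."""

    mode: str                # "tss" or "genebody"
    positions: np.ndarray    # bp offsets (tss) or percent-of-body (genebody)
    mean_signal: np.ndarray


def metagene_profile(track: SignalTrack, genes: list[GeneModel], mode: str,
                     cfg: PipelineConfig,
                     step_bp: Optional[int] = None) -> MetageneProfile:
    """Average track signal across genes, strand-aware.

    ``tss`` mode samples the track at offsets -flank..+flank around each
    TSS (step defaults to the track bin size, capped at the flank) and
    reverses minus-strand genes. ``genebody`` mode rescales each gene body
    to ``genebody_nbins`` equal fractions and takes the length-weighted mean
    per fraction, again reversing minus-strand genes.
    """
    if not genes:
        raise ValidationError("metagene_profile requires a non-empty gene list")
    if mode == "tss":
        flank = cfg.metagene_flank_bp
        step = step_bp if step_bp is not None else min(track.bin_size, flank)
        step = max(1, min(step, flank))
        offsets = np.arange(-flank, flank + 1, step)
        acc = np.zeros(len(offsets))
        for g in genes:
            sign = 1 if g.strand == "+" else -1
            vals = [track.value_at(g.chrom, g.tss + sign * int(o))
                    for o in offsets]
            acc += np.array(vals)
        return MetageneProfile("tss", offsets, acc / len(genes))
    if mode == "genebody":
        nb = cfg.genebody_nbins
        acc = np.zeros(nb)
        for g in genes:
            edges = np.rint(np.linspace(g.start, g.end, nb + 1)).astype(int)
            vals = np.array([
                track.mean_over(g.chrom, edges[i],
                                max(edges[i] + 1, edges[i + 1]))
                for i in range(nb)
            ])
            if g.strand == "-":
                vals = vals[::-1]
            acc += vals
        positions = (np.arange(nb) + 0.5) / nb * 100.0
        return MetageneProfile("genebody", positions, acc / len(genes))
    raise ValidationError(f"unknown metagene mode {mode!r}")


@dataclass
class StratificationResult:
    """Mean log2(KO/WT) of binding, 5hmC and expression by TET1 status."""

    per_gene: pd.DataFrame  # index gene_id; columns tet1_bound + 3 log2 ratios
    group_means: pd.DataFrame  # index {TET1_bound, not_TET1_bound}


def stratify_expression_by_binding(genes: list[GeneModel],
                                   assignment: PromoterAssignment,
                                   tracks: dict[str, SignalTrack],
                                   expr: ExpressionMatrix,
                                   cfg: PipelineConfig,
                                   timepoint_days: int = 0) -> StratificationResult:
    """Average KO/WT log2 changes for TET1-bound vs not-bound genes.

    Binding and 5hmC use promoter-window mean track signal; expression uses
    the replicate-mean abundance at the naive (day-0) stage by default. All
    ratios share the config pseudocount.
    """
    for key in ("tet1_wt", "tet1_ko", "hmc_wt", "hmc_ko"):
        if key not in tracks:
            raise ValidationError(f"missing track {key!r}")
    pc = cfg.pseudocount
    expr_wt = expr.mean_by("WT", timepoint_days)
    expr_ko = expr.mean_by("KO", timepoint_days)
    rows = {}
    bound = assignment.target_genes
    for g in genes:
        lo, hi = g.promoter(cfg.promoter_flank_bp)
        vals = {}
        for label, wt_key, ko_key in (("binding", "tet1_wt", "tet1_ko"),
                                      ("hmc", "hmc_wt", "hmc_ko")):
            wt = tracks[wt_key].mean_over(g.chrom, lo, hi)
            ko = tracks[ko_key].mean_over(g.chrom, lo, hi)
            vals[f"log2_{label}"] = math.log2((ko + pc) / (wt + pc))
        vals["log2_expression"] = math.log2(
            (expr_ko[g.gene_id] + pc) / (expr_wt[g.gene_id] + pc))
        vals["tet1_bound"] = g.gene_id in bound
        rows[g.gene_id] = vals
    per_gene = pd.DataFrame.from_dict(rows, orient="index")
    per_gene.index.name = "gene_id"
    groups = per_gene.groupby(
        per_gene["tet1_bound"].map({True: "TET1_bound", False: "not_TET1_bound"})
    )[["log2_binding", "log2_hmc", "log2_expression"]].mean()
    groups.index.name = "group"
    return StratificationResult(per_gene, groups)


@dataclass
class ContingencyTable:
    """2x2 association between differential expression and binding loss."""

    table: np.ndarray  # rows: DE yes/no; cols: reduced yes/no
    chi2: float
    p_value: float
    warning: Optional[str] = None


def chi_squared_association(de_genes: set[str], reduced_genes: set[str],
                            universe: set[str],
                            correction: bool = False) -> ContingencyTable:
    """Pearson chi-squared (df = 1, no Yates correction by default).

    Tests whether differentially expressed genes are over-represented among
    genes with reduced promoter binding.
    """
    if not de_genes <= universe:
        raise ValidationError("de_genes not a subset of the universe")
    if not reduced_genes <= universe:
        raise ValidationError("reduced_genes not a subset of the universe")
    a = len(de_genes & reduced_genes)
    b = len(de_genes - reduced_genes)
    c = len(reduced_genes - de_genes)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    warning = None
    if table.sum() == 0 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        # degenerate margins: independence is vacuous
        return ContingencyTable(table, 0.0, 1.0, "degenerate margins")
    chi2, p, _df, expected = stats.chi2_contingency(table, correction=correction)
    if (expected < 1).any():
        warning = "expected cell count < 1; chi-squared approximation unreliable"
    return ContingencyTable(table, float(chi2), float(p), warning)
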