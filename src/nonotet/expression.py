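"""Differential expression and the two-stage 9-square rescue classification.

The classification places each gene on a 3x3 grid by thresholded log2
fold-change on two comparison axes. Stage 1 contrasts day 12 vs day 0 of
differentiation in WT (x) against the same contrast in Nono KO (y) and keeps
genes that move in WT but not in KO; stage 2 re-tests the survivors with the
rescue line (KO+WT) on x against KO on y. Genes passing both stages change
with differentiation only when NONO is present — the "NONO-dependent" sets.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ExpressionMatrix,
    PipelineConfig,
    ValidationError,
)

#: row-major 3x3 grid; rows = y category (up / ns / down, top to bottom),
#: columns = x category (down / ns / up, left to right)
GRID_LETTERS = {
    (-1, 1): "A", (0, 1): "B", (1, 1): "C",
    (-1, 0): "D", (0, 0): "E", (1, 0): "F",
    (-1, -1): "G", (0, -1): "H", (1, -1): "I",
}


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so abundances sum to one million.

    TPM_gs = FPKM_gs / sum_g FPKM_gs * 1e6.
    """
    if m.unit != "FPKM":
        raise ValidationError(f"expected FPKM input, got {m.unit}")
    sums = m.values.sum(axis=0)
    zero = sums.index[sums <= 0]
    if len(zero):
        raise ValidationError(f"all-zero sample column(s): {list(zero)}")
    values = m.values / sums * 1e6
    return ExpressionMatrix(values, list(m.samples), unit="TPM")


def differential_expression(m: ExpressionMatrix,
                            samples_a: list[str], samples_b: list[str],
                            cfg: PipelineConfig) -> pd.DataFrame:
    """Per-gene fold-change and Welch-test p-value for B over A.

    log2fc = log2((mean_b + pc) / (mean_a + pc)) on the abundance scale;
    the p-value comes from Welch's two-sample t-test on log2(value + pc).
    Status is ``up`` when log2fc > log2(fc_cutoff) and p < p_cutoff (strict),
    ``down`` symmetrically, else ``ns``. Returns a DataFrame indexed by
    gene_id with columns log2fc, p_value, mean_a, mean_b, status.
    """
    for side, cols in (("A", samples_a), ("B", samples_b)):
        if len(cols) < 2:
            raise ValidationError(f"side {side} needs >=2 replicates, got {len(cols)}")
        missing = [c for c in cols if c not in m.values.columns]
        if missing:
            raise ValidationError(f"unknown sample(s) on side {side}: {missing}")
    pc = cfg.pseudocount
    a = m.values[samples_a].to_numpy()
    b = m.values[samples_b].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_b + pc) / (mean_a + pc))
    _t, p = stats.ttest_ind(np.log2(b + pc), np.log2(a + pc),
                            axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)  # zero-variance degenerate case
    cut = cfg.cutoff_log2
    status = np.where((log2fc > cut) & (p < cfg.p_cutoff), "up",
                      np.where((log2fc < -cut) & (p < cfg.p_cutoff), "down", "ns"))
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "mean_a": mean_a, "mean_b": mean_b,
         "status": status},
        index=m.values.index,
    )


@dataclass
class NineSquareResult:
    """Per-gene grid letters A..I for one pair of fold-change axes."""

    labels: pd.Series  # index gene_id, values in "A".."I"
    cutoff_log2: float
    x_name: str = "x"
    y_name: str = "y"

    def genes_in(self, *letters: str) -> set[str]:
        return set(self.labels.index[self.labels.isin(letters)])

    def counts(self) -> dict[str, int]:
        c = self.labels.value_counts()
        return {letter: int(c.get(letter, 0)) for letter in "ABCDEFGHI"}


def classify_nine_square(fc_x: pd.Series, fc_y: pd.Series,
                         cutoff_log2: float,
                         x_name: str = "x", y_name: str = "y") -> NineSquareResult:
    """Assign each gene its 3x3 grid letter from two log2 fold-change axes.

    A gene is "up" on an axis when fc > cutoff_log2, "down" when
    fc < -cutoff_log2, neutral otherwise; letters follow the row-major grid
    in :data:`GRID_LETTERS` (so F and I collect genes up on x but not up on
    y, A and D genes down on x but not down on y).
    """
    if set(fc_x.index) != set(fc_y.index):
        raise ValidationError("fold-change axes cover different gene universes")
    fc_y = fc_y.reindex(fc_x.index)
    bad = fc_x.index[~(np.isfinite(fc_x) & np.isfinite(fc_y))]
    if len(bad):
        raise ValidationError(f"non-finite fold-change for: {list(bad[:10])}")

    def cat(v: np.ndarray) -> np.ndarray:
        return np.where(v > cutoff_log2, 1, np.where(v < -cutoff_log2, -1, 0))

    cx, cy = cat(fc_x.to_numpy()), cat(fc_y.to_numpy())
    letters = [GRID_LETTERS[(int(x), int(y))] for x, y in zip(cx, cy)]
    return NineSquareResult(pd.Series(letters, index=fc_x.index),
                            cutoff_log2, x_name, y_name)


@dataclass
class DependentGeneSets:
    """Rescue-validated dependent genes and the stage-1 intermediates."""

    stage1_up: set[str]     # up with differentiation in WT, not in KO (F u I)
    stage1_down: set[str]   # down in WT, not in KO (A u D)
    up_dependent: set[str]    # stage-1 up genes also up in rescue vs KO
    down_dependent: set[str]  # stage-1 down genes also down in rescue vs KO

    def __post_init__(self) -> None:
        if not self.up_dependent <= self.stage1_up:
            raise ValidationError("up_dependent must be a subset of stage1_up")
        if not self.down_dependent <= self.stage1_down:
            raise ValidationError("down_dependent must be a subset of stage1_down")
        if self.up_dependent & self.down_dependent:
            raise ValidationError("up/down dependent sets overlap")


def select_dependent_genes(de_wt: pd.DataFrame, de_ko: pd.DataFrame,
                           de_rescue: pd.DataFrame,
                           cfg: PipelineConfig) -> DependentGeneSets:
    """Two-stage selection of NONO-dependent genes.

    All three DE tables are the day12-vs-day0 contrast within one genotype
    (WT, KO, rescue). Stage 1: 9-square with WT on x and KO on y; F u I are
    up-in-WT-only, A u D down-in-WT-only. Stage 2: survivors re-classified
    with the rescue on x and KO on y; membership in F u I (resp. A u D) of
    that grid confirms dependence. Grid placement uses fold-change alone.
    """
    universe = set(de_wt.index)
    if set(de_ko.index) != universe or set(de_rescue.index) != universe:
        raise ValidationError("DE tables cover different gene universes")
    cut = cfg.cutoff_log2
    stage1 = classify_nine_square(de_wt["log2fc"], de_ko["log2fc"], cut,
                                  "WT_d12_vs_d0", "KO_d12_vs_d0")
    stage2 = classify_nine_square(de_rescue["log2fc"], de_ko["log2fc"], cut,
                                  "KO_WT_d12_vs_d0", "KO_d12_vs_d0")
    s1_up, s1_down = stage1.genes_in("F", "I"), stage1.genes_in("A", "D")
    s2_up, s2_down = stage2.genes_in("F", "I"), stage2.genes_in("A", "D")
    return DependentGeneSets(
        stage1_up=s1_up, stage1_down=s1_down,
        up_dependent=s1_up & s2_up, down_dependent=s1_down & s2_down,
    )


@dataclass
class TrajectoryMatrix:
    """Replicate-averaged expression over time, raw and unit-scaled.

    Rows are (gene_id, genotype) pairs, columns timepoints. ``scaled``
    maps each row affinely onto [0, 1]; a constant row maps to all zeros.
    """

    means: pd.DataFrame
    scaled: pd.DataFrame


def scale_trajectories(m: ExpressionMatrix,
                       genes: list[str] | None = None) -> TrajectoryMatrix:
    """Average replicates per (genotype, timepoint), then min-max scale."""
    if genes is None:
        genes = m.genes
    missing = set(genes) - set(m.genes)
    if missing:
        raise ValidationError(f"genes absent from matrix: {sorted(missing)[:5]}")
    genotypes = sorted({s.genotype for s in m.samples})
    timepoints = sorted({s.timepoint_days for s in m.samples})
    rows = {}
    for g in genotypes:
        cols = {t: m.mean_by(g, t) for t in timepoints}
        sub = pd.DataFrame(cols).loc[genes]
        for gid in genes:
            rows[(gid, g)] = sub.loc[gid].to_numpy()
    means = pd.DataFrame.from_dict(rows, orient="index", columns=timepoints)
    means.index = pd.MultiIndex.from_tuples(means.index,
                                            names=["gene_id", "genotype"])
    arr = means.to_numpy(dtype=float)
    lo = arr.min(axis=1, keepdims=True)
    span = arr.max(axis=1, keepdims=True) - lo
    # spans at rounding-noise level (means of unequal replicate counts can
    # differ by ulps even for a truly constant gene) count as constant
    tol = 1e-9 * np.maximum(np.abs(arr).max(axis=1, keepdims=True), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > tol, (arr - lo) / span, 0.0)
    return TrajectoryMatrix(means, pd.DataFrame(scaled, index=means.index,
                                                columns=means.columns))


def top_differential(de: pd.DataFrame, k: int) -> list[str]:
    """Top-k genes by |log2fc|, ties by ascending p then gene id."""
    if k > len(de):
        raise ValidationError(f"k={k} exceeds universe size {len(de)}")
    # stable sort on a lexicographically pre-sorted frame gives the tie-break
    ranked = de.assign(_abs=de["log2fc"].abs()).sort_index().sort_values(
        by=["_abs", "p_value"], ascending=[False, True], kind="mergesort")
    return list(ranked.index[:k])
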