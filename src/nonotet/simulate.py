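"""Seeded generators for a toy genome with planted ground truth.

The simulator emulates the statistical structure of a rescue-design
differentiation experiment: three genotypes (WT, Nono KO, KO rescued with
wild-type NONO) sampled at days 0/3/6/12 with 3 replicates at day 0 and 2 at
the later timepoints, plus coupled TET1 / NONO / 5hmC chromatin peak sets in
which a configurable fraction of TET1-bound promoters loses most of its
occupancy in the KO. Every generated quantity is deterministic under the
config seed; changing only the seed preserves all count-level contracts.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GeneModel,
    Interval,
    PeakSet,
    SignalTrack,
    ValidationError,
    default_sample_design,
)
from . import io as nio

DEPENDENCE_CLASSES = ("dep_up", "dep_down", "null_up", "null_down", "flat")


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions.

    frac_nono_cobound echoes the observed 85% NONO/TET1 peak co-occupancy
    and frac_reduced_in_ko the "more than half of TET1 binding events
    reduced" observation. effect_log2fc = 2 plants a 4-fold differentiation
    ramp; binding_effect_log2 is the KO-only naive-state expression
    down-shift on genes whose promoter TET1 peak is reduced, which couples
    day-0 differential expression to binding loss.
    """

    n_chroms: int = 2
    chrom_len_bp: int = 60_000_000
    n_genes: int = 5000
    n_dep_up: int = 500
    n_dep_down: int = 300
    n_null_up: int = 400
    n_null_down: int = 300
    frac_tet1_bound: float = 0.5
    frac_reduced_in_ko: float = 0.6
    frac_nono_cobound: float = 0.85
    nono_to_tet1_ratio: float = 0.15
    bg_peaks_per_gene_peak: float = 0.2
    effect_log2fc: float = 2.0
    binding_effect_log2: float = 1.0
    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    track_bin_bp: int = 500
    track_noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_tet1_bound", "frac_reduced_in_ko",
                     "frac_nono_cobound"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        n_labelled = (self.n_dep_up + self.n_dep_down
                      + self.n_null_up + self.n_null_down)
        if n_labelled > self.n_genes:
            raise ValidationError(
                f"{n_labelled} labelled genes exceed n_genes={self.n_genes}"
            )
        if self.n_chroms < 1 or self.n_genes < 0:
            raise ValidationError("n_chroms >= 1 and n_genes >= 0 required")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_len_bp for i in range(self.n_chroms)}


@dataclass
class TruthLabels:
    """Planted per-gene and per-peak labels the recovery tests score against.

    ``genes`` columns: dependence (dep_up/dep_down/null_up/null_down/flat),
    tet1_bound (bool), reduced_in_ko (bool; implies tet1_bound).
    ``nono_cobound`` holds, per NONO peak (in PeakSet order), whether it was
    placed on a TET1 peak.
    """

    genes: pd.DataFrame  # index gene_id
    nono_cobound: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        bad = self.genes["reduced_in_ko"] & ~self.genes["tet1_bound"]
        if bad.any():
            raise ValidationError("reduced_in_ko gene that is not tet1_bound")

    def gene_set(self, dependence: str) -> set[str]:
        return set(self.genes.index[self.genes["dependence"] == dependence])


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def simulate_genome(cfg: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping genes (lengths U(2, 20) kb, spacing >= 1 kb).

    Genes are spread over each chromosome by drawing the intergenic slack
    from a Dirichlet so the toy genome has realistic gene deserts.
    """
    rng = _rng(cfg, 1)
    genes: list[GeneModel] = []
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    gid = 0
    for ci, n in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        if n == 0:
            continue
        lengths = rng.integers(2000, 20_001, size=n)
        free = cfg.chrom_len_bp - int(lengths.sum()) - 1000 * (n + 1)
        if free < 0:
            raise ValidationError(
                f"cannot pack {n} genes into {chrom} of {cfg.chrom_len_bp} bp; "
                "increase chrom_len_bp"
            )
        gaps = 1000 + np.floor(free * rng.dirichlet(np.ones(n + 1))).astype(int)
        strands = rng.choice(["+", "-"], size=n)
        pos = 0
        for j in range(n):
            pos += int(gaps[j])
            start, end = pos, pos + int(lengths[j])
            gid += 1
            genes.append(GeneModel(f"g{gid:05d}", chrom, start, end, strands[j]))
            pos = end
    return genes


def _ramp(effect: float, day: int) -> float:
    # linear in time over the 12-day course
    return effect * day / 12.0


def simulate_expression(genes: list[GeneModel],
                        cfg: SimulationConfig) -> tuple[ExpressionMatrix, TruthLabels]:
    """Plant dependence classes and draw the 27-sample FPKM matrix.

    Baseline log2 FPKM ~ N(baseline_log2_mean, baseline_log2_sd^2) per gene.
    dep_up genes ramp by effect_log2fc from day 0 to day 12 in WT and the
    rescue but stay flat in KO; dep_down mirror this downward; null_up /
    null_down ramp identically in all three genotypes; flat genes are
    constant. Genes whose promoter TET1 peak will be reduced in KO carry an
    additional constant -binding_effect_log2 shift in KO only. Replicate
    noise N(0, noise_sd_log2^2) is added on the log2 scale, then
    exponentiated.
    """
    if not genes:
        raise ValidationError("simulate_expression requires a non-empty annotation")
    rng = _rng(cfg, 2)
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)

    order = rng.permutation(n)
    dependence = np.full(n, "flat", dtype=object)
    splits = np.cumsum([cfg.n_dep_up, cfg.n_dep_down, cfg.n_null_up, cfg.n_null_down])
    dependence[order[: splits[0]]] = "dep_up"
    dependence[order[splits[0]: splits[1]]] = "dep_down"
    dependence[order[splits[1]: splits[2]]] = "null_up"
    dependence[order[splits[2]: splits[3]]] = "null_down"

    n_bound = int(round(cfg.frac_tet1_bound * n))
    bound_idx = rng.choice(n, size=n_bound, replace=False)
    tet1_bound = np.zeros(n, dtype=bool)
    tet1_bound[bound_idx] = True
    n_reduced = int(round(cfg.frac_reduced_in_ko * n_bound))
    reduced = np.zeros(n, dtype=bool)
    if n_reduced:
        reduced[rng.choice(bound_idx, size=n_reduced, replace=False)] = True

    truth = TruthLabels(pd.DataFrame(
        {"dependence": dependence, "tet1_bound": tet1_bound,
         "reduced_in_ko": reduced},
        index=pd.Index(gene_ids, name="gene_id"),
    ))

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    samples = default_sample_design()
    cols = {}
    sign = {"dep_up": 1.0, "dep_down": -1.0, "null_up": 1.0,
            "null_down": -1.0, "flat": 0.0}
    for s in samples:
        ramp = _ramp(cfg.effect_log2fc, s.timepoint_days)
        effect = np.array([
            0.0 if (dep in ("dep_up", "dep_down") and s.genotype == "KO")
            else sign[dep] * ramp
            for dep in dependence
        ])
        shift = np.where(reduced & (s.genotype == "KO"),
                         -cfg.binding_effect_log2, 0.0)
        noise = rng.normal(0.0, cfg.noise_sd_log2, size=n)
        cols[s.sample_id] = np.exp2(baseline + effect + shift + noise)
    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionMatrix(values, samples, unit="FPKM"), truth


def _intergenic_gaps(genes: list[GeneModel], chrom_sizes: dict[str, int],
                     margin: int, width: int) -> tuple[list[tuple[str, int, int]], np.ndarray]:
    """Spans at least ``margin`` bp from any gene with room for ``width`` bp."""
    gaps: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[GeneModel]] = {c: [] for c in chrom_sizes}
    for g in genes:
        by_chrom[g.chrom].append(g)
    for chrom, size in chrom_sizes.items():
        gs = sorted(by_chrom[chrom], key=lambda g: g.start)
        bounds = [0] + [x for g in gs for x in (g.start, g.end)] + [size]
        for lo, hi in zip(bounds[::2], bounds[1::2]):
            s, e = lo + margin, hi - margin - width
            if e > s:
                gaps.append((chrom, s, e))
    weights = np.array([e - s for _c, s, e in gaps], dtype=float)
    return gaps, weights / weights.sum()


def _background_peaks(rng, n: int, genes, chrom_sizes, margin: int,
                      avoid: Optional[list[Interval]] = None) -> list[Interval]:
    out: list[Interval] = []
    avoid = avoid or []
    gaps, p = _intergenic_gaps(genes, chrom_sizes, margin, width=1300)
    tries = 0
    while len(out) < n and tries < 50 * max(n, 1):
        tries += 1
        width = int(rng.integers(600, 1201))
        gi = rng.choice(len(gaps), p=p)
        chrom, lo, hi = gaps[gi]
        start = int(rng.integers(lo, hi))
        cand = Interval(chrom, start, start + width,
                        signal=float(rng.gamma(4.0, 5.0)))
        if any(cand.overlaps(iv) for iv in avoid + out):
            continue
        out.append(cand)
    return out


@dataclass
class ChromatinBundle:
    """Peak sets and matching binned tracks from one simulation."""

    peaks: dict[str, PeakSet]           # TET1_WT, TET1_KO, NONO_WT, hmC_WT, hmC_KO
    tracks: dict[str, SignalTrack]
    tet1_gene_ids: list[str]            # gene_id per gene-associated TET1 peak,
                                        # "" for background peaks (PeakSet order)


def simulate_chromatin(genes: list[GeneModel], truth: TruthLabels,
                       cfg: SimulationConfig) -> ChromatinBundle:
    """Generate coupled TET1/NONO/5hmC peak sets and binned signal tracks.

    Every tet1_bound gene receives a TET1 peak centred on its TSS (width
    U(600, 1200) bp, Gamma(4, 5) signal). The same intervals appear in the
    KO set with signal multiplied by U(0.05, 0.45) when the gene is
    reduced_in_ko, else U(0.8, 1.2). A Poisson count of intergenic
    background peaks is shared by both genotypes. NONO peaks sit on a
    frac_nono_cobound subset of TET1 peaks plus independent background that
    avoids TET1 intervals; 5hmC mirrors TET1 with multiplicative lognormal
    coupling noise. Tracks paint peak signal into fixed bins
    (length-weighted) and add Exponential background noise.
    """
    rng = _rng(cfg, 3)
    chrom_sizes = cfg.chrom_sizes
    gmap = {g.gene_id: g for g in genes}

    tet1_wt: list[Interval] = []
    tet1_ko: list[Interval] = []
    owners: list[str] = []
    for gene_id, row in truth.genes.iterrows():
        if not row["tet1_bound"]:
            continue
        g = gmap[gene_id]
        width = int(rng.integers(600, 1201))
        start = max(0, g.tss - width // 2)
        sig = float(rng.gamma(4.0, 5.0))
        factor = (rng.uniform(0.05, 0.45) if row["reduced_in_ko"]
                  else rng.uniform(0.8, 1.2))
        tet1_wt.append(Interval(g.chrom, start, start + width, signal=sig,
                                name=gene_id))
        tet1_ko.append(Interval(g.chrom, start, start + width,
                                signal=sig * float(factor), name=gene_id))
        owners.append(gene_id)

    n_bg = int(rng.poisson(cfg.bg_peaks_per_gene_peak * max(len(tet1_wt), 1)))
    bg = _background_peaks(rng, n_bg, genes, chrom_sizes, margin=3000)
    for iv in bg:
        tet1_wt.append(iv)
        tet1_ko.append(Interval(iv.chrom, iv.start, iv.end,
                                signal=iv.signal * float(rng.uniform(0.8, 1.2)),
                                name=iv.name))
        owners.append("")

    order = sorted(range(len(tet1_wt)),
                   key=lambda i: (tet1_wt[i].chrom, tet1_wt[i].start))
    tet1_wt = [tet1_wt[i] for i in order]
    tet1_ko = [tet1_ko[i] for i in order]
    owners = [owners[i] for i in order]

    # NONO: cobound peaks share a TET1 interval; background avoids all TET1
    n_nono = int(round(cfg.nono_to_tet1_ratio * len(tet1_wt)))
    n_cob = min(int(round(cfg.frac_nono_cobound * n_nono)), len(tet1_wt))
    cob_idx = rng.choice(len(tet1_wt), size=n_cob, replace=False)
    nono: list[Interval] = []
    cobound_flags: list[bool] = []
    for i in cob_idx:
        host = tet1_wt[i]
        nono.append(Interval(host.chrom, host.start, host.end,
                             signal=float(rng.gamma(4.0, 5.0))))
        cobound_flags.append(True)
    nono_bg = _background_peaks(rng, n_nono - n_cob, genes, chrom_sizes,
                                margin=3000, avoid=tet1_wt)
    nono.extend(nono_bg)
    cobound_flags.extend([False] * len(nono_bg))
    norder = sorted(range(len(nono)), key=lambda i: (nono[i].chrom, nono[i].start))
    nono = [nono[i] for i in norder]
    truth.nono_cobound = np.array([cobound_flags[i] for i in norder])

    # 5hmC mirrors TET1 with multiplicative coupling noise
    def mirror(src: list[Interval]) -> list[Interval]:
        noise = rng.lognormal(0.0, 0.3, size=len(src))
        return [Interval(iv.chrom, iv.start, iv.end,
                         signal=iv.signal * float(f), name=iv.name)
                for iv, f in zip(src, noise)]

    peaks = {
        "TET1_WT": PeakSet("TET1_WT", tet1_wt),
        "TET1_KO": PeakSet("TET1_KO", tet1_ko),
        "NONO_WT": PeakSet("NONO_WT", nono),
        "hmC_WT": PeakSet("hmC_WT", mirror(tet1_wt)),
        "hmC_KO": PeakSet("hmC_KO", mirror(tet1_ko)),
    }

    tracks = {}
    for name, ps in peaks.items():
        bb = cfg.track_bin_bp
        values = {c: np.zeros(int(np.ceil(n / bb)))
                  for c, n in chrom_sizes.items()}
        for iv in ps:
            v = values[iv.chrom]
            for b in range(iv.start // bb, (iv.end - 1) // bb + 1):
                bs = b * bb
                be = min(bs + bb, chrom_sizes[iv.chrom])
                w = min(iv.end, be) - max(iv.start, bs)
                v[b] += iv.signal * w / (be - bs)
        for c in values:
            values[c] += rng.exponential(cfg.track_noise_scale,
                                         size=len(values[c]))
        tracks[name] = SignalTrack(bb, dict(chrom_sizes), values)
    return ChromatinBundle(peaks, tracks, owners)


def simulate_gene_sets(truth: TruthLabels, cfg: SimulationConfig,
                       n_random: int = 3) -> dict[str, set[str]]:
    """Toy "pathway" collections: two enriched in the planted dependent
    genes plus random sets, for exercising over-representation analysis."""
    rng = _rng(cfg, 4)
    universe = list(truth.genes.index)
    sets: dict[str, set[str]] = {}
    for name, dep in (("pathway_neuro_up", "dep_up"),
                      ("pathway_dev_down", "dep_down")):
        members = list(truth.gene_set(dep))
        if not members:
            continue
        k = max(1, len(members) // 3)
        chosen = set(rng.choice(members, size=min(k, len(members)), replace=False))
        chosen |= set(rng.choice(universe, size=k // 4 + 1, replace=False))
        sets[name] = chosen
    for i in range(n_random):
        k = int(rng.integers(100, 301))
        k = min(k, len(universe))
        sets[f"pathway_random_{i + 1}"] = set(
            rng.choice(universe, size=k, replace=False))
    return sets


@dataclass
class SimulatedStudy:
    cfg: SimulationConfig
    genes: list[GeneModel]
    expression: ExpressionMatrix
    chromatin: ChromatinBundle
    truth: TruthLabels
    gene_sets: dict[str, set[str]]


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run all generators in memory (no files)."""
    genes = simulate_genome(cfg)
    expr, truth = simulate_expression(genes, cfg)
    chromatin = simulate_chromatin(genes, truth, cfg)
    gene_sets = simulate_gene_sets(truth, cfg)
    return SimulatedStudy(cfg, genes, expr, chromatin, truth, gene_sets)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_all(cfg: SimulationConfig, out_dir, force: bool = False) -> Path:
    """Write the full bundle (annotation, expression, peaks, tracks, truth,
    gene sets, chrom sizes) plus a checksum manifest to ``out_dir``."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(
            f"output directory {out} is not empty (use force=True / --force)"
        )
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(cfg)

    nio.write_bed(study.genes, out / "genes.bed")
    nio.write_expression_tsv(study.expression, out / "expression_fpkm.tsv")
    nio.write_chrom_sizes(cfg.chrom_sizes, out / "chrom.sizes")
    for name, ps in study.chromatin.peaks.items():
        nio.write_bed(ps, out / f"peaks_{name.lower()}.bed")
    for name, tr in study.chromatin.tracks.items():
        nio.write_bedgraph(tr, out / f"track_{name.lower()}.bedgraph")

    study.truth.genes.to_csv(out / "truth_labels.tsv", sep="\t")
    nono = study.chromatin.peaks["NONO_WT"]
    with open(out / "truth_nono_peaks.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tcobound_nono\n")
        for iv, cb in zip(nono, study.truth.nono_cobound):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{int(cb)}\n")
    with open(out / "truth_tet1_peak_genes.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tgene_id\n")
        for iv, gid in zip(study.chromatin.peaks["TET1_WT"],
                           study.chromatin.tet1_gene_ids):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gid}\n")
    with open(out / "gene_sets.tsv", "w") as fh:
        fh.write("set_name\tgene_id\n")
        for name in sorted(study.gene_sets):
            for gid in sorted(study.gene_sets[name]):
                fh.write(f"{name}\t{gid}\n")
    with open(out / "sim_config.txt", "w") as fh:
        for key, value in asdict(cfg).items():
            fh.write(f"{key} = {value}\n")

    names = sorted(p.name for p in out.iterdir() if p.name != "MANIFEST.tsv")
    with open(out / "MANIFEST.tsv", "w") as fh:
        fh.write("file\tsha256\n")
        for name in names:
            fh.write(f"{name}\t{_sha256(out / name)}\n")
    return out
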