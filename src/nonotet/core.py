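"""Core domain types shared across the pipeline.

Coordinates are BED-native throughout: 0-based, half-open ``[start, end)``.
The TSS of a minus-strand gene is ``end - 1``. Chromosome names are taken
verbatim from input files; a mismatch between files is an error, never a
silent drop.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "KO", "KO_WT")
TIMEPOINTS = (0, 3, 6, 12)

#: replicate counts per (genotype, timepoint): 3 at day 0, 2 at days 3/6/12
REPLICATES = {0: 3, 3: 2, 6: 2, 12: 2}


class ValidationError(ValueError):
    """An object violates a domain invariant."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic extent and strand, with the derived TSS.

    The unit for promoter assignment and metagene profiles.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"{self.gene_id}: negative start {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"{self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: unknown strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on +, ``end - 1`` on -."""
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self, flank: int) -> tuple[int, int]:
        """Promoter window ``[tss - flank, tss + flank)``, clipped at 0.

        The window always contains at least the TSS base itself.
        """
        lo = max(0, self.tss - flank)
        hi = max(self.tss + flank, self.tss + 1)
        return lo, hi


_SAMPLE_ID_RE = re.compile(r"^(WT|KO|KO_WT)_d(\d+)_r(\d+)$")


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one RNA-seq sample: genotype x timepoint x replicate."""

    sample_id: str
    genotype: str
    timepoint_days: int
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        if self.timepoint_days not in TIMEPOINTS:
            raise ValidationError(
                f"timepoint {self.timepoint_days} not in {TIMEPOINTS}"
            )
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")

    @classmethod
    def make(cls, genotype: str, timepoint_days: int, replicate: int) -> "SampleMeta":
        sid = f"{genotype}_d{timepoint_days}_r{replicate}"
        return cls(sid, genotype, timepoint_days, replicate)

    @classmethod
    def from_id(cls, sample_id: str) -> "SampleMeta":
        m = _SAMPLE_ID_RE.match(sample_id)
        if m is None:
            raise ValidationError(
                f"sample id {sample_id!r} does not encode metadata "
                "(expected GENOTYPE_d<day>_r<rep>, e.g. KO_WT_d12_r2)"
            )
        return cls(sample_id, m.group(1), int(m.group(2)), int(m.group(3)))


def default_sample_design() -> list[SampleMeta]:
    """The 27-sample design: 3 genotypes x (3 reps at day 0, 2 at 3/6/12)."""
    out = []
    for g in GENOTYPES:
        for t in TIMEPOINTS:
            for r in range(1, REPLICATES[t] + 1):
                out.append(SampleMeta.make(g, t, r))
    return out


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance table (FPKM or TPM) with sample metadata."""

    values: pd.DataFrame  # index: gene_id, columns: sample_id
    samples: list[SampleMeta]
    unit: str = "FPKM"

    def __post_init__(self) -> None:
        if self.unit not in ("FPKM", "TPM"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dups[:5])}")
        sids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != sids:
            raise ValidationError("sample metadata does not match matrix columns")
        if len(set((s.genotype, s.timepoint_days, s.replicate) for s in self.samples)) != len(sids):
            raise ValidationError("duplicate (genotype, timepoint, replicate) triple")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite abundance value")
        if (arr < 0).any():
            raise ValidationError("negative abundance value")
        if self.unit == "TPM":
            sums = arr.sum(axis=0)
            if not np.allclose(sums, 1e6, rtol=1e-6):
                raise ValidationError("TPM columns must sum to 1e6")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def sample_ids(self, genotype: Optional[str] = None,
                   timepoint_days: Optional[int] = None) -> list[str]:
        """Sample ids matching the given genotype and/or timepoint."""
        out = []
        for s in self.samples:
            if genotype is not None and s.genotype != genotype:
                continue
            if timepoint_days is not None and s.timepoint_days != timepoint_days:
                continue
            out.append(s.sample_id)
        return out

    def mean_by(self, genotype: str, timepoint_days: int) -> pd.Series:
        """Per-gene mean abundance over replicates of one condition."""
        cols = self.sample_ids(genotype, timepoint_days)
        if not cols:
            raise ValidationError(
                f"no samples for genotype={genotype} day={timepoint_days}"
            )
        return self.values[cols].mean(axis=1)


@dataclass(frozen=True)
class Interval:
    """A genomic interval with an occupancy signal (one ChIP/hMeDIP peak)."""

    chrom: str
    start: int
    end: int
    signal: float = 0.0
    name: str = ""
    score_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative coordinate {self.start}")
        if self.start >= self.end:
            raise ValidationError(f"start {self.start} >= end {self.end}")

    def overlaps(self, other: "Interval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class PeakSet:
    """A named peak collection, sorted by (chrom, start)."""

    name: str
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        key = [(iv.chrom, iv.start, iv.end) for iv in self.intervals]
        if key != sorted(key):
            raise ValidationError(
                f"PeakSet {self.name!r} is not sorted by (chrom, start)"
            )

    @classmethod
    def build(cls, name: str, intervals: list[Interval]) -> "PeakSet":
        """Construct from intervals in any order (sorts them)."""
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return cls(name, ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


@dataclass
class SignalTrack:
    """Fixed-bin genome-wide coverage; the last bin of a chrom may be partial."""

    bin_size: int
    chrom_sizes: dict[str, int]
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        if set(self.values) != set(self.chrom_sizes):
            raise ValidationError("values and chrom_sizes cover different chroms")
        for chrom, size in self.chrom_sizes.items():
            want = self.n_bins(chrom)
            v = np.asarray(self.values[chrom], dtype=float)
            if len(v) != want:
                raise ValidationError(
                    f"{chrom}: {len(v)} bins, expected {want} for length {size}"
                )
            if (v < 0).any():
                raise ValidationError(f"{chrom}: negative signal value")
            self.values[chrom] = v

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_sizes[chrom] / self.bin_size)

    def same_binning(self, other: "SignalTrack") -> bool:
        return (self.bin_size == other.bin_size
                and self.chrom_sizes == other.chrom_sizes)

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal of the bin containing ``pos`` (0 outside the chromosome)."""
        if chrom not in self.values:
            raise ValidationError(f"chrom {chrom!r} absent from track")
        if pos < 0 or pos >= self.chrom_sizes[chrom]:
            return 0.0
        return float(self.values[chrom][pos // self.bin_size])

    def rebin(self, new_bin_size: int) -> "SignalTrack":
        """Coarsen to a multiple of the current bin size (weighted mean)."""
        if new_bin_size == self.bin_size:
            return self
        if new_bin_size % self.bin_size:
            raise ValidationError(
                f"new bin size {new_bin_size} is not a multiple of "
                f"{self.bin_size}"
            )
        k = new_bin_size // self.bin_size
        values = {}
        for chrom, size in self.chrom_sizes.items():
            v = self.values[chrom]
            widths = np.full(len(v), float(self.bin_size))
            if size % self.bin_size:
                widths[-1] = size % self.bin_size
            nb_new = math.ceil(size / new_bin_size)
            pad = nb_new * k - len(v)
            wsum = np.concatenate([v * widths, np.zeros(pad)])
            wtot = np.concatenate([widths, np.zeros(pad)])
            values[chrom] = (wsum.reshape(nb_new, k).sum(1)
                             / wtot.reshape(nb_new, k).sum(1))
        return SignalTrack(new_bin_size, dict(self.chrom_sizes), values)

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean bin value over ``[start, end)``.

        Base pairs outside the chromosome contribute 0.
        """
        if chrom not in self.values:
            raise ValidationError(f"chrom {chrom!r} absent from track")
        if start >= end:
            raise ValidationError("empty span")
        size = self.chrom_sizes[chrom]
        lo, hi = max(0, start), min(end, size)
        if lo >= hi:
            return 0.0
        v = self.values[chrom]
        b0, b1 = lo // self.bin_size, (hi - 1) // self.bin_size
        total = 0.0
        for b in range(b0, b1 + 1):
            bs, be = b * self.bin_size, min((b + 1) * self.bin_size, size)
            w = min(be, hi) - max(bs, lo)
            total += v[b] * w
        return total / (end - start)


@dataclass
class PipelineConfig:
    """Tunable thresholds of the analysis.

    fc_cutoff / p_cutoff are the differential-expression cut-offs
    (fold-change > 1.5 and P < 0.05, strict inequalities).
    reduced_log2_cutoff flags a peak as "reduced" when
    log2((KO + pseudocount) / (WT + pseudocount)) falls at or below it.
    bin_size_bp is the genome-wide correlation bin; quant_bin_bp the finer
    bin used to quantify signal over individual peaks, promoter windows and
    metagene positions (10-kb bins would dilute sub-kb peaks ~10-fold and
    compress occupancy ratios toward zero).
    """

    fc_cutoff: float = 1.5
    p_cutoff: float = 0.05
    promoter_flank_bp: int = 2000
    reduced_log2_cutoff: float = -1.0
    bin_size_bp: int = 10_000
    quant_bin_bp: int = 500
    metagene_flank_bp: int = 2500
    genebody_nbins: int = 100
    pseudocount: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fc_cutoff", "p_cutoff", "promoter_flank_bp",
                     "bin_size_bp", "quant_bin_bp", "metagene_flank_bp",
                     "genebody_nbins", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.reduced_log2_cutoff >= 0:
            raise ValidationError("reduced_log2_cutoff must be negative")

    @property
    def cutoff_log2(self) -> float:
        """log2 of the fold-change cutoff (the 9-square grid line)."""
        return math.log2(self.fc_cutoff)
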