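"""Readers and writers for the plain-text genomic formats the pipeline consumes.

BED3/BED6 for peaks and gene models, bedGraph for binned signal, TSV for
expression matrices, and a flat ``key = value`` config file. All files are
tab-separated UTF-8 with '.' decimal separators.
"""
from __future__ import annotations

import dataclasses
import logging
import sys
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GeneModel,
    Interval,
    PeakSet,
    PipelineConfig,
    SampleMeta,
    SignalTrack,
    ValidationError,
)

log = logging.getLogger("nonotet")


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


def setup_logging(quiet: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.WARNING if quiet else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


def _parse_coords(fields: list[str], path: str, lineno: int) -> tuple[str, int, int]:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    if start < 0 or start >= end:
        raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
    return fields[0], start, end


def read_bed(path: Union[str, Path], kind: str = "peaks"):
    """Read a BED3/BED6 file as a :class:`PeakSet` or a gene list.

    For ``kind="genes"`` column 4 is the gene_id (auto-named when absent),
    column 6 the strand (default ``+``); the TSS follows from the strand.
    For ``kind="peaks"`` a numeric column 5 is parsed into ``signal``.
    Records are returned sorted by (chrom, start).
    """
    if kind not in ("peaks", "genes"):
        raise ValueError(f"kind must be 'peaks' or 'genes', got {kind!r}")
    path = Path(path)
    peaks: list[Interval] = []
    genes: list[GeneModel] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = _parse_coords(fields, str(path), lineno)
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            if kind == "peaks":
                signal = 0.0
                if len(fields) > 4:
                    try:
                        signal = float(fields[4])
                    except ValueError:
                        signal = 0.0
                peaks.append(Interval(chrom, start, end, signal=signal, name=name))
            else:
                strand = fields[5] if len(fields) > 5 else "+"
                if strand not in ("+", "-"):
                    raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
                gid = name or f"gene_{lineno}"
                if gid in seen_ids:
                    raise ParseError(f"{path}:{lineno}: duplicate gene id {gid!r}")
                seen_ids.add(gid)
                genes.append(GeneModel(gid, chrom, start, end, strand))
    if kind == "peaks":
        return PeakSet.build(path.stem, peaks)
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


def write_bed(records, path: Union[str, Path]) -> None:
    """Write a :class:`PeakSet` or gene list as BED6 (round-trips read_bed)."""
    path = Path(path)
    with open(path, "w") as fh:
        if isinstance(records, PeakSet):
            for i, iv in enumerate(records):
                name = iv.name or f"{records.name}_{i}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{iv.signal:.6g}\t.\n")
        else:
            for g in records:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_bedgraph(path: Union[str, Path], bin_size: int,
                  chrom_sizes: dict[str, int]) -> SignalTrack:
    """Bin a bedGraph into a :class:`SignalTrack`.

    Each bin's value is the length-weighted mean of overlapping bedGraph
    records, with uncovered base pairs contributing 0. Input intervals must
    not overlap; intervals beyond ``chrom_sizes`` are an error.
    """
    path = Path(path)
    sums = {c: np.zeros(int(np.ceil(n / bin_size))) for c, n in chrom_sizes.items()}
    covered: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: fewer than 4 columns")
            chrom, start, end = _parse_coords(fields, str(path), lineno)
            if chrom not in chrom_sizes:
                raise ParseError(f"{path}:{lineno}: unknown chrom {chrom!r}")
            if end > chrom_sizes[chrom]:
                raise ParseError(
                    f"{path}:{lineno}: interval beyond {chrom!r} "
                    f"(length {chrom_sizes[chrom]})"
                )
            try:
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
            covered[chrom].append((start, end))
            s = sums[chrom]
            for b in range(start // bin_size, (end - 1) // bin_size + 1):
                w = min(end, (b + 1) * bin_size) - max(start, b * bin_size)
                s[b] += value * w
    for chrom, spans in covered.items():
        spans.sort()
        for (s0, e0), (s1, _e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ParseError(
                    f"{path}: overlapping intervals on {chrom} near {s1}"
                )
    values = {}
    for chrom, size in chrom_sizes.items():
        nb = int(np.ceil(size / bin_size))
        widths = np.full(nb, float(bin_size))
        if size % bin_size:
            widths[-1] = size % bin_size
        values[chrom] = sums[chrom] / widths
    return SignalTrack(bin_size, dict(chrom_sizes), values)


def write_bedgraph(track: SignalTrack, path: Union[str, Path]) -> None:
    """Write one record per bin (zero-valued bins included)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.chrom_sizes):
            size = track.chrom_sizes[chrom]
            for b, v in enumerate(track.values[chrom]):
                s = b * track.bin_size
                e = min(s + track.bin_size, size)
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.8g}\n")


def read_expression_tsv(path: Union[str, Path]) -> ExpressionMatrix:
    """Read a gene x sample FPKM table.

    The first column is the gene id; the remaining column headers are sample
    ids that embed the metadata as ``GENOTYPE_d<day>_r<rep>``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    try:
        samples = [SampleMeta.from_id(c) for c in df.columns]
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        return ExpressionMatrix(df.astype(float), samples, unit="FPKM")
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_expression_tsv(m: ExpressionMatrix, path: Union[str, Path]) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.8g")


def read_chrom_sizes(path: Union[str, Path]) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom\\tlength'")
            out[fields[0]] = int(fields[1])
    return out


def write_chrom_sizes(chrom_sizes: dict[str, int], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")


def read_config(path: Union[str, Path]) -> dict[str, str]:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            out[key] = value
    return out


def pipeline_config_from_file(path: Union[str, Path]) -> PipelineConfig:
    raw = read_config(path)
    kwargs = {}
    fields = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    for key, value in raw.items():
        if key not in fields:
            raise ParseError(f"{path}: unknown config key {key!r}")
        typ = PipelineConfig.__dataclass_fields__[key].type
        cast = int if "int" in str(typ) else float
        kwargs[key] = cast(value)
    return PipelineConfig(**kwargs)
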