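"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open ``[start, end)``, the
convention of BED and PAF.  Human-readable reports use 1-based inclusive
coordinates; the conversion lives in exactly one pair of functions,
:func:`to_report_coords` and :func:`from_report_coords`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlap_len(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def to_report_coords(interval: GenomeInterval) -> tuple[str, int, int]:
    """0-based half-open -> 1-based inclusive, for human-readable reports."""
    return interval.chrom, interval.start + 1, interval.end


def from_report_coords(chrom: str, start1: int, end1: int) -> GenomeInterval:
    """1-based inclusive -> 0-based half-open."""
    return GenomeInterval(chrom, start1 - 1, end1)


@dataclass(frozen=True)
class AlignmentBlock:
    """One pairwise alignment segment (a PAF line), query onto target."""

    qchrom: str
    qstart: int
    qend: int
    tchrom: str
    tstart: int
    tend: int
    strand: str
    block_len: int = 0
    qlen: int = 0
    tlen: int = 0

    def __post_init__(self) -> None:
        if self.qend - self.qstart < 1:
            raise ValueError("query interval must have length >= 1")
        if self.tend - self.tstart < 1:
            raise ValueError("target interval must have length >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def q_interval(self) -> GenomeInterval:
        return GenomeInterval(self.qchrom, self.qstart, self.qend)

    @property
    def t_interval(self) -> GenomeInterval:
        return GenomeInterval(self.tchrom, self.tstart, self.tend)


@dataclass(frozen=True)
class DepthWindow:
    """Mean read depth over one fixed-width genomic window."""

    interval: GenomeInterval
    mean_depth: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean_depth) or self.mean_depth < 0:
            raise ValueError(
                f"depth must be finite and >= 0, got {self.mean_depth}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, SEQUENCE), ...]``, uppercased.

    Order is preserved; duplicate headers raise; an empty file raises.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header: {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write records wrapped at 60 columns (round-trips with read_fasta)."""
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# PAF


def read_paf(path: str | Path) -> list[AlignmentBlock]:
    """Parse a 12+-column PAF file into alignment blocks.

    PAF coordinates are 0-based half-open and kept verbatim.  A line with
    fewer than 12 columns raises with its line number.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 12 PAF columns, "
                    f"got {len(fields)}"
                )
            blocks.append(
                AlignmentBlock(
                    qchrom=fields[0],
                    qlen=int(fields[1]),
                    qstart=int(fields[2]),
                    qend=int(fields[3]),
                    strand=fields[4],
                    tchrom=fields[5],
                    tlen=int(fields[6]),
                    tstart=int(fields[7]),
                    tend=int(fields[8]),
                    block_len=int(fields[10]),
                )
            )
    return blocks


def write_paf(path: str | Path, blocks: Iterable[AlignmentBlock]) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            nmatch = b.block_len or (b.qend - b.qstart)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.qchrom, b.qlen, b.qstart, b.qend, b.strand,
                        b.tchrom, b.tlen, b.tstart, b.tend,
                        nmatch, nmatch, 60,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Depth BED (4-column: chrom, start, end, mean depth)


def read_depth_bed(path: str | Path) -> list[DepthWindow]:
    windows: list[DepthWindow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 BED columns"
                )
            depth = float(fields[3])
            if not math.isfinite(depth) or depth < 0:
                raise ValueError(
                    f"{path}: line {lineno}: depth must be finite and >= 0"
                )
            windows.append(
                DepthWindow(
                    GenomeInterval(fields[0], int(fields[1]), int(fields[2])),
                    depth,
                )
            )
    return windows


def write_depth_bed(path: str | Path, windows: Iterable[DepthWindow]) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f"{w.interval.chrom}\t{w.interval.start}\t{w.interval.end}"
                f"\t{w.mean_depth:.4f}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrix TSV (gene rows, sample columns, header row)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV.  Ragged rows or NaN cells raise."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: matrix contains missing/NaN cells")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate gene ids: {dups[:5]}")
    return df


def write_matrix_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Truth JSON (see haplotax.synthetic.SyntheticTruth)


def _interval_to_json(iv: GenomeInterval) -> list:
    return [iv.chrom, iv.start, iv.end]


def _interval_from_json(v: Sequence) -> GenomeInterval:
    return GenomeInterval(str(v[0]), int(v[1]), int(v[2]))


def write_truth_json(path: str | Path, truth: "Mapping | object") -> None:
    """Serialize a SyntheticTruth (or its dict form) to JSON."""
    if hasattr(truth, "to_dict"):
        truth = truth.to_dict()
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth_json(path: str | Path):
    from haplotax.synthetic import SyntheticTruth

    with open(path) as fh:
        payload = json.load(fh)
    return SyntheticTruth.from_dict(payload)


__all__ = [
    "GenomeInterval",
    "AlignmentBlock",
    "DepthWindow",
    "to_report_coords",
    "from_report_coords",
    "read_fasta",
    "write_fasta",
    "read_paf",
    "write_paf",
    "read_depth_bed",
    "write_depth_bed",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_truth_json",
    "write_truth_json",
]
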