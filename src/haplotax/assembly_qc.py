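"""Assembly accounting: gaps, telomeres, T2T status, NX curves, QV, anchoring.

These are the bookkeeping statistics used to describe a chromosome-scale
phased assembly: maximal N-runs are gaps; telomeric repeat arrays at the
chromosome termini plus zero gaps means a telomere-to-telomere (T2T)
chromosome; the NX curve summarises contig continuity; the Phred-scaled
consensus quality value (QV) converts to an expected base-error rate.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from haplotax._util import revcomp, round_half_up
from haplotax.io_formats import GenomeInterval

DEFAULT_TELOMERE_MOTIF = "TTTAGGG"  # canonical plant telomere repeat


@dataclass
class ChromosomeRecord:
    """One haplotype chromosome with its gap and telomere annotations."""

    id: str
    haplotype: str = ""
    sequence: str | None = None
    length: int = 0
    gaps: list[GenomeInterval] = field(default_factory=list)
    telomere_left: bool = False
    telomere_right: bool = False

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if self.length and self.length != len(self.sequence):
                raise ValueError("length disagrees with sequence")
            self.length = len(self.sequence)

    @property
    def gap_count(self) -> int:
        return len(self.gaps)


@dataclass
class AssemblyStats:
    """Whole-assembly summary statistics."""

    total_len: int = 0
    contig_n_values: dict[int, int] = field(default_factory=dict)
    gap_count: int = 0
    qv: float | None = None
    anchored_len: int = 0

    @property
    def n50(self) -> int:
        return self.contig_n_values[50]


def scan_gaps(sequence: str, min_n_run: int = 10) -> list[GenomeInterval]:
    """Maximal runs of N of length >= min_n_run, as sorted intervals.

    The number of intervals is the assembly's gap count.  The default
    threshold of 10 avoids counting isolated ambiguous bases as gaps.
    """
    if min_n_run < 1:
        raise ValueError("min_n_run must be >= 1")
    if not sequence:
        return []
    seq = sequence.upper()
    pattern = re.compile("N{%d,}" % min_n_run)
    return [
        GenomeInterval("seq", m.start(), m.end()) for m in pattern.finditer(seq)
    ]


def nx_curve(
    contig_lengths: Sequence[int],
    fractions: Sequence[int] = (10, 20, 30, 40, 50, 60, 70, 80, 90),
) -> dict[int, int]:
    """NX values: the contig length at which the descending cumulative sum
    first reaches X% of the total (the common assembly-stats convention).
    """
    if not contig_lengths:
        raise ValueError("need at least one contig length")
    if any(l <= 0 for l in contig_lengths):
        raise ValueError("contig lengths must be positive")
    lengths = sorted(contig_lengths, reverse=True)
    total = sum(lengths)
    curve: dict[int, int] = {}
    for x in fractions:
        threshold = total * x / 100.0
        cum = 0
        for l in lengths:
            cum += l
            if cum >= threshold:
                curve[x] = l
                break
    return curve


def telomere_scan(
    sequence: str,
    motif: str = DEFAULT_TELOMERE_MOTIF,
    terminal_window: int = 10_000,
    min_copies: int = 10,
) -> tuple[bool, bool]:
    """Detect telomeric repeat arrays in the first/last terminal_window bp.

    An end is telomeric iff the motif (or its reverse complement, so both
    strands are covered) occurs at least min_copies times within the
    terminal window.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if terminal_window < len(motif):
        raise ValueError("terminal_window must be >= motif length")
    seq = sequence.upper()
    motif = motif.upper()
    rc = revcomp(motif)

    def _hits(segment: str) -> int:
        return segment.count(motif) + (segment.count(rc) if rc != motif else 0)

    left = _hits(seq[:terminal_window]) >= min_copies
    right = _hits(seq[-terminal_window:]) >= min_copies
    return left, right


def t2t_status(record: ChromosomeRecord) -> bool:
    """True iff the chromosome has telomeres at both ends and zero gaps."""
    return record.telomere_left and record.telomere_right and record.gap_count == 0


def annotate_chromosome(
    chrom_id: str,
    sequence: str,
    haplotype: str = "",
    min_n_run: int = 10,
    motif: str = DEFAULT_TELOMERE_MOTIF,
    terminal_window: int = 10_000,
    min_copies: int = 10,
) -> ChromosomeRecord:
    """Run gap and telomere scans and return the annotated record."""
    gaps = [
        GenomeInterval(chrom_id, g.start, g.end)
        for g in scan_gaps(sequence, min_n_run)
    ]
    left, right = telomere_scan(sequence, motif, terminal_window, min_copies)
    return ChromosomeRecord(
        id=chrom_id,
        haplotype=haplotype,
        sequence=sequence,
        gaps=gaps,
        telomere_left=left,
        telomere_right=right,
    )


def qv_to_errors_per_mbp(qv: float) -> float:
    """Convert a Phred-scaled consensus QV to expected errors per Mbp.

    QV 60 is exactly 1 error per Mbp: 10^(-QV/10) errors/base * 1e6.
    """
    if not math.isfinite(qv):
        raise ValueError("qv must be finite")
    if qv <= 0:
        raise ValueError("qv must be positive")
    return 10 ** (-qv / 10.0) * 1e6


def anchoring_rate(anchored_len: int, total_len: int) -> float:
    """Percent of assembled sequence anchored onto chromosomes, 1 decimal."""
    if total_len <= 0:
        raise ValueError("total_len must be positive")
    if not (0 <= anchored_len <= total_len):
        raise ValueError("need 0 <= anchored_len <= total_len")
    return round_half_up(100.0 * anchored_len / total_len, 1)


def n50_ratio(n50_a: float, n50_b: float) -> float:
    """Contig-N50 ratio between two assemblies, rounded to 1 decimal."""
    if n50_b <= 0 or n50_a <= 0:
        raise ValueError("both N50 values must be positive")
    return round_half_up(n50_a / n50_b, 1)


def nested_percent(outer_pct: float, inner_pct: float) -> int:
    """Share of a whole given as a percent of a percent, rounded to integer.

    E.g. repeats at 84% of the genome of which 69% are LTR elements gives
    an LTR genome share of 58%.
    """
    return int(round_half_up(outer_pct * inner_pct / 100.0, 0))


def combine_stats(stats: Iterable[AssemblyStats]) -> AssemblyStats:
    """Aggregate additive statistics (lengths, gap counts) across haplotypes.

    NX curves and QV are not additive and are left unset.
    """
    out = AssemblyStats()
    for s in stats:
        out.total_len += s.total_len
        out.gap_count += s.gap_count
        out.anchored_len += s.anchored_len
    return out


def assembly_stats(
    records: Sequence[ChromosomeRecord],
    contig_lengths: Sequence[int] | None = None,
    qv: float | None = None,
    anchored_len: int | None = None,
) -> AssemblyStats:
    """Summarise a set of annotated chromosomes.

    contig_lengths default to chromosome lengths split at gaps (gaps break
    contigs); anchored_len defaults to the total chromosome length.
    """
    total = sum(r.length for r in records)
    if contig_lengths is None:
        contig_lengths = []
        for r in records:
            prev = 0
            for g in sorted(r.gaps):
                if g.start > prev:
                    contig_lengths.append(g.start - prev)
                prev = g.end
            if r.length > prev:
                contig_lengths.append(r.length - prev)
    return AssemblyStats(
        total_len=total,
        contig_n_values=nx_curve(contig_lengths),
        gap_count=sum(r.gap_count for r in records),
        qv=qv,
        anchored_len=total if anchored_len is None else anchored_len,
    )


__all__ = [
    "ChromosomeRecord",
    "AssemblyStats",
    "scan_gaps",
    "nx_curve",
    "telomere_scan",
    "t2t_status",
    "annotate_chromosome",
    "qv_to_errors_per_mbp",
    "anchoring_rate",
    "n50_ratio",
    "nested_percent",
    "combine_stats",
    "assembly_stats",
    "DEFAULT_TELOMERE_MOTIF",
]
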