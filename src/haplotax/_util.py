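"""Small shared numerics: report rounding, reverse complement, interval union."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

from haplotax.io_formats import GenomeInterval

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ndigits, the convention of printed reports.

    Python's builtin round() is banker's rounding; reported percentages and
    ratios follow the half-up convention instead (1.075 -> 1.08 at 2 digits).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def merge_intervals(intervals: Iterable[GenomeInterval]) -> list[GenomeInterval]:
    """Union of intervals via a sorted sweep, per chromosome."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomeInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomeInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def union_length(intervals: Iterable[GenomeInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))
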