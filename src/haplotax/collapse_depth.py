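"""Read-depth collapse calling and ZW sex-chromosome candidate ranking.

A *collapsed* region is present in both haplotypes but assembled only once,
so HiFi reads from both copies pile onto the single assembled copy and the
windowed mapping depth doubles.  Calling such windows, estimating the copy
number, and adding back the missing copies yields collapse-corrected
chromosome lengths.  Homologous-pair length differences on the corrected
lengths — after excluding pairs rearranged by interchromosomal
translocations — rank candidate sex-chromosome pairs; in a female
(ZW-heterogametic) sample the longer haplotype is the W candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from haplotax._util import round_half_up
from haplotax.io_formats import DepthWindow, GenomeInterval


@dataclass(frozen=True)
class CollapseCall:
    """A merged run of high-depth windows with an estimated copy number."""

    interval: GenomeInterval
    est_copies: int

    def __post_init__(self) -> None:
        if self.est_copies < 2:
            raise ValueError("est_copies must be >= 2")

    @property
    def extra_len(self) -> int:
        """Assembly length missing due to the collapse."""
        return len(self.interval) * (self.est_copies - 1)


@dataclass
class CorrectedLengthRow:
    """Collapse-corrected lengths for one homologous chromosome pair."""

    pair_id: str
    assembled_len_1: int
    assembled_len_2: int
    extra_1: int = 0
    extra_2: int = 0

    @property
    def corrected_1(self) -> int:
        return self.assembled_len_1 + self.extra_1

    @property
    def corrected_2(self) -> int:
        return self.assembled_len_2 + self.extra_2

    @property
    def diff_bp(self) -> int:
        return abs(self.corrected_1 - self.corrected_2)

    @property
    def diff_pct_1(self) -> float:
        return 100.0 * self.diff_bp / self.corrected_1

    @property
    def diff_pct_2(self) -> float:
        return 100.0 * self.diff_bp / self.corrected_2

    @property
    def diff_pct(self) -> float:
        """Ranking statistic: the larger of the two percentage differences."""
        return max(self.diff_pct_1, self.diff_pct_2)


def modal_depth(windows: Sequence[DepthWindow]) -> float:
    """Baseline (haploid-equivalent) depth: the histogram mode.

    Freedman–Diaconis binning; returns the midpoint of the tallest bin.
    Robust against the high-depth tail contributed by collapsed regions.
    """
    if len(windows) < 10:
        raise ValueError("need at least 10 windows to estimate a mode")
    depths = np.asarray([w.mean_depth for w in windows], dtype=float)
    if np.all(depths == 0):
        raise ValueError("all window depths are zero")
    counts, edges = np.histogram(depths, bins="fd")
    i = int(np.argmax(counts))
    return float((edges[i] + edges[i + 1]) / 2.0)


def call_collapsed(
    windows: Sequence[DepthWindow],
    baseline: float,
    factor: float = 1.75,
    merge: bool = True,
) -> list[CollapseCall]:
    """Flag windows with depth >= factor * baseline and merge adjacent ones.

    factor defaults to 1.75: a fully collapsed two-copy region maps at ~2x
    the baseline depth, and 1.75 tolerates sampling noise while staying well
    above the haploid band.  est_copies = round(depth / baseline), clamped
    to >= 2.  The >= comparison is inclusive at the threshold.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if factor <= 1:
        raise ValueError("factor must be > 1")
    threshold = factor * baseline

    ordered = sorted(
        windows, key=lambda w: (w.interval.chrom, w.interval.start)
    )
    flagged = [w for w in ordered if w.mean_depth >= threshold]

    calls: list[CollapseCall] = []
    run: list[DepthWindow] = []

    def _flush() -> None:
        if not run:
            return
        iv = GenomeInterval(
            run[0].interval.chrom, run[0].interval.start, run[-1].interval.end
        )
        # depth-weighted mean over the merged run, weighted by window size
        sizes = np.array([len(w.interval) for w in run], dtype=float)
        depths = np.array([w.mean_depth for w in run], dtype=float)
        mean_depth = float(np.average(depths, weights=sizes))
        copies = max(2, int(round(mean_depth / baseline)))
        calls.append(CollapseCall(iv, copies))
        run.clear()

    if not merge:
        for w in flagged:
            copies = max(2, int(round(w.mean_depth / baseline)))
            calls.append(CollapseCall(w.interval, copies))
        return calls

    for w in flagged:
        if (
            run
            and w.interval.chrom == run[-1].interval.chrom
            and w.interval.start == run[-1].interval.end
        ):
            run.append(w)
        else:
            _flush()
            run.append(w)
    _flush()
    return calls


def collapse_rate(calls: Iterable[CollapseCall], genome_len: int) -> float:
    """Percent of the assembly inside collapse calls, to 2 decimals."""
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    total = sum(len(c.interval) for c in calls)
    return round_half_up(100.0 * total / genome_len, 2)


def extra_length_by_chrom(calls: Iterable[CollapseCall]) -> dict[str, int]:
    """Total extra (unassembled) length implied by the calls, per chromosome."""
    extra: dict[str, int] = {}
    for c in calls:
        extra[c.interval.chrom] = extra.get(c.interval.chrom, 0) + c.extra_len
    return extra


def corrected_lengths(
    assembled: Mapping[str, tuple[int, int]],
    extra: Mapping[str, tuple[int, int]] | None = None,
) -> list[CorrectedLengthRow]:
    """Collapse-corrected length table for homologous chromosome pairs.

    assembled maps pair id -> (hap1 length, hap2 length); extra maps pair
    id -> per-haplotype collapse extra lengths (default 0).  Corrected
    length = assembled + extra.
    """
    extra = extra or {}
    rows = []
    for pair_id in sorted(assembled):
        l1, l2 = assembled[pair_id]
        e1, e2 = extra.get(pair_id, (0, 0))
        rows.append(CorrectedLengthRow(pair_id, l1, l2, e1, e2))
    return rows


def rank_sex_candidates(
    rows: Sequence[CorrectedLengthRow],
    excluded_chroms: Iterable[str] = (),
    female_sample: bool = True,
) -> list[dict]:
    """Rank homologous pairs by corrected length difference (descending).

    Pairs carrying interchromosomal translocations are excluded first (their
    length difference reflects the rearrangement, not sex divergence).  The
    top-ranked pair is the sex-chromosome candidate; for a female sample the
    longer haplotype is labelled W and the shorter Z.
    """
    excluded = set(excluded_chroms)
    known = {r.pair_id for r in rows}
    if not excluded <= known:
        raise ValueError(f"excluded chroms not in rows: {excluded - known}")
    kept = [r for r in rows if r.pair_id not in excluded]
    if not kept:
        raise ValueError("all chromosome pairs were excluded")
    kept.sort(key=lambda r: (-r.diff_pct, r.pair_id))

    out = []
    for r in kept:
        if female_sample:
            w_hap, z_hap = (1, 2) if r.corrected_1 >= r.corrected_2 else (2, 1)
        else:
            w_hap = z_hap = None
        out.append(
            {
                "pair_id": r.pair_id,
                "diff_bp": r.diff_bp,
                "diff_pct_1": round_half_up(r.diff_pct_1, 2),
                "diff_pct_2": round_half_up(r.diff_pct_2, 2),
                "W_haplotype": w_hap,
                "Z_haplotype": z_hap,
            }
        )
    return out


__all__ = [
    "CollapseCall",
    "CorrectedLengthRow",
    "modal_depth",
    "call_collapsed",
    "collapse_rate",
    "extra_length_by_chrom",
    "corrected_lengths",
    "rank_sex_candidates",
]
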