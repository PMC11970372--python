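"""Structural-variant classification between haplotypes from alignment blocks.

The classifier works on pairwise alignment blocks (PAF) between the two
haplotypes of a phased assembly.  A syntenic backbone is first chained per
chromosome pair (weighted longest-increasing-subsequence over + strand
blocks, collinear in both coordinate systems).  Against that backbone:

- a - strand block inside its homologous pair is an inversion (INV);
- a block aligning outside its chromosome's backbone partner is a
  translocation (TRANS);
- an off-backbone + strand block whose target interval mostly re-covers
  backbone-covered target sequence is a duplication (DUP);
- a gap between consecutive backbone blocks present on only one side is an
  insertion (INS, query side) or deletion (DEL, target side).

Calls shorter than ``min_sv_len`` (default 50 bp, inclusive) are dropped.
Nested or redundant candidates are resolved by precedence
INV > TRANS > DUP > INS/DEL, longest first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from haplotax._util import merge_intervals, round_half_up, union_length
from haplotax.io_formats import AlignmentBlock, GenomeInterval

_PRECEDENCE = {"INV": 0, "TRANS": 1, "DUP": 2, "INS": 3, "DEL": 3}


@dataclass(frozen=True)
class SVCall:
    """One classified structural variant between the haplotypes."""

    sv_type: str
    q_interval: GenomeInterval | None  # None when degenerate (DEL)
    t_interval: GenomeInterval | None  # None when degenerate (INS)
    length: int

    def __post_init__(self) -> None:
        if self.sv_type not in _PRECEDENCE:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.length < 1:
            raise ValueError("SV length must be >= 1")


@dataclass
class SyntenyChains:
    """Backbone chains per (query chrom, target chrom) pair."""

    chains: dict[tuple[str, str], list[AlignmentBlock]]
    partner: dict[str, str]  # query chrom -> its backbone target chrom

    def backbone_blocks(self) -> set[AlignmentBlock]:
        out: set[AlignmentBlock] = set()
        for (q, t), chain in self.chains.items():
            if self.partner.get(q) == t:
                out.update(chain)
        return out


def _weighted_lis(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Max-total-length subset of blocks increasing in both q and t."""
    blocks = sorted(blocks, key=lambda b: (b.qstart, b.qend, b.tstart, b.tend))
    n = len(blocks)
    best = [0] * n
    prev = [-1] * n
    for i, b in enumerate(blocks):
        w = b.qend - b.qstart
        best[i] = w
        for j in range(i):
            a = blocks[j]
            if a.qend <= b.qstart and a.tend <= b.tstart:
                cand = best[j] + w
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    if n == 0:
        return []
    i = max(range(n), key=lambda k: (best[k], -k))
    chain = []
    while i != -1:
        chain.append(blocks[i])
        i = prev[i]
    chain.reverse()
    return chain


def chain_syntenic(
    blocks: Sequence[AlignmentBlock],
    min_block: int = 50,
    max_gap: int | None = None,
) -> SyntenyChains:
    """Chain + strand blocks into a syntenic backbone per chromosome pair.

    The chain is the highest-coverage set of blocks collinear in both query
    and target coordinates (length-weighted LIS).  Each query chromosome's
    backbone partner is the target chromosome whose chain covers the most
    query sequence.  max_gap, when given, splits chains across gaps larger
    than it in either coordinate (unused by default).
    """
    groups: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        if b.strand != "+" or (b.qend - b.qstart) < min_block:
            continue
        groups.setdefault((b.qchrom, b.tchrom), []).append(b)

    chains: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for key in sorted(groups):
        chain = _weighted_lis(groups[key])
        if max_gap is not None and len(chain) > 1:
            split: list[AlignmentBlock] = [chain[0]]
            for a, b in zip(chain, chain[1:]):
                if (
                    b.qstart - a.qend > max_gap
                    or b.tstart - a.tend > max_gap
                ):
                    break
                split.append(b)
            chain = split
        chains[key] = chain

    partner: dict[str, str] = {}
    coverage: dict[str, int] = {}
    for (q, t), chain in sorted(chains.items()):
        cov = sum(b.qend - b.qstart for b in chain)
        if cov > coverage.get(q, -1):
            coverage[q] = cov
            partner[q] = t
    return SyntenyChains(chains, partner)


def classify_svs(
    blocks: Sequence[AlignmentBlock],
    chains: SyntenyChains | None = None,
    min_sv_len: int = 50,
    dup_overlap: float = 0.5,
) -> list[SVCall]:
    """Classify structural variants against the syntenic backbone.

    Deterministic and invariant to the input order of blocks.
    """
    if chains is None:
        chains = chain_syntenic(blocks, min_block=min_sv_len)
    backbone = chains.backbone_blocks()
    partner = chains.partner

    # target coverage of the backbone, per target chromosome
    t_cov = merge_intervals(b.t_interval for b in backbone)

    candidates: list[SVCall] = []
    for b in sorted(
        blocks, key=lambda b: (b.qchrom, b.qstart, b.tchrom, b.tstart)
    ):
        if b in backbone:
            continue
        qlen = b.qend - b.qstart
        cross = partner.get(b.qchrom) is not None and partner[b.qchrom] != b.tchrom
        if cross:
            candidates.append(SVCall("TRANS", b.q_interval, b.t_interval, qlen))
        elif b.strand == "-":
            candidates.append(SVCall("INV", b.q_interval, b.t_interval, qlen))
        else:
            covered = sum(
                b.t_interval.overlap_len(iv) for iv in t_cov
            )
            if covered >= dup_overlap * (b.tend - b.tstart):
                candidates.append(
                    SVCall("DUP", b.q_interval, b.t_interval, qlen)
                )

    # one-sided gaps between consecutive backbone blocks -> INS / DEL
    for (q, t), chain in sorted(chains.chains.items()):
        if partner.get(q) != t:
            continue
        for a, b in zip(chain, chain[1:]):
            qgap = b.qstart - a.qend
            tgap = b.tstart - a.tend
            if qgap >= min_sv_len and tgap < min_sv_len:
                candidates.append(
                    SVCall(
                        "INS",
                        GenomeInterval(q, a.qend, b.qstart),
                        None,
                        qgap,
                    )
                )
            elif tgap >= min_sv_len and qgap < min_sv_len:
                candidates.append(
                    SVCall(
                        "DEL",
                        None,
                        GenomeInterval(t, a.tend, b.tstart),
                        tgap,
                    )
                )

    candidates = [c for c in candidates if c.length >= min_sv_len]

    # precedence resolution: INV > TRANS > DUP > INS/DEL, longest first
    def _overlap_frac(c: SVCall, k: SVCall) -> float:
        frac = 0.0
        if c.q_interval is not None and k.q_interval is not None:
            frac = max(
                frac, c.q_interval.overlap_len(k.q_interval) / c.length
            )
        if c.t_interval is not None and k.t_interval is not None:
            frac = max(
                frac, c.t_interval.overlap_len(k.t_interval) / c.length
            )
        return frac

    ordered = sorted(
        candidates,
        key=lambda c: (
            _PRECEDENCE[c.sv_type],
            -c.length,
            (c.q_interval or c.t_interval).chrom,
            (c.q_interval or c.t_interval).start,
        ),
    )
    kept: list[SVCall] = []
    for c in ordered:
        if all(_overlap_frac(c, k) < 0.5 for k in kept):
            kept.append(c)
    kept.sort(
        key=lambda c: (
            (c.t_interval or c.q_interval).chrom,
            (c.t_interval or c.q_interval).start,
            c.sv_type,
        )
    )
    return kept


def sv_type_counts(calls: Iterable[SVCall]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.sv_type] = counts.get(c.sv_type, 0) + 1
    return counts


def unaligned_fraction(
    region: GenomeInterval, blocks: Sequence[AlignmentBlock]
) -> tuple[int, float]:
    """Unaligned (nonhomologous) bp within a query region, and its percent.

    unaligned = |region| - |union of block query intervals within region|;
    the percent is reported to 1 decimal.
    """
    if len(region) == 0:
        raise ValueError("region must be non-empty")
    clipped = []
    for b in blocks:
        if b.qchrom != region.chrom:
            continue
        s = max(b.qstart, region.start)
        e = min(b.qend, region.end)
        if s < e:
            clipped.append(GenomeInterval(region.chrom, s, e))
    covered = union_length(clipped)
    unaligned = len(region) - covered
    return unaligned, round_half_up(100.0 * unaligned / len(region), 1)


def sv_genome_fraction(calls: Iterable[SVCall], genome_len: int) -> float:
    """Percent of the genome inside SV calls, to 1 decimal."""
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    total = sum(c.length for c in calls)
    return round_half_up(100.0 * total / genome_len, 1)


def translocated_pairs(
    calls: Iterable[SVCall], pair_of: Mapping[str, str] | None = None
) -> set[str]:
    """Homologous-pair ids touched by interchromosomal translocations.

    pair_of maps a haplotype chromosome name to its pair id; by default the
    ``<pair>_h<k>`` naming convention is stripped.
    """

    def _pair(chrom: str) -> str:
        if pair_of is not None:
            return pair_of[chrom]
        return chrom.rsplit("_h", 1)[0]

    out: set[str] = set()
    for c in calls:
        if c.sv_type != "TRANS":
            continue
        if c.q_interval is not None:
            out.add(_pair(c.q_interval.chrom))
        if c.t_interval is not None:
            out.add(_pair(c.t_interval.chrom))
    return out


__all__ = [
    "SVCall",
    "SyntenyChains",
    "chain_syntenic",
    "classify_svs",
    "sv_type_counts",
    "unaligned_fraction",
    "sv_genome_fraction",
    "translocated_pairs",
]
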