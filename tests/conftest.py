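"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use the dumbest possible algorithms
(per-base loops, bitmaps, two-pass covariance) so they stay independent of
the implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from haplotax import synthetic


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_gap_scan(seq: str, min_n_run: int) -> list[tuple[int, int]]:
    """Per-base scan for maximal N-runs of length >= min_n_run."""
    seq = seq.upper()
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "N":
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_n_run:
                runs.append((start, i))
            start = None
    if start is not None and len(seq) - start >= min_n_run:
        runs.append((start, len(seq)))
    return runs


def brute_motif_count(segment: str, motif: str) -> int:
    """Non-overlapping motif count by stepping through the string."""
    n = 0
    i = 0
    while True:
        j = segment.find(motif, i)
        if j == -1:
            return n
        n += 1
        i = j + len(motif)


def brute_telomere_scan(
    seq: str, motif: str, terminal_window: int, min_copies: int
) -> tuple[bool, bool]:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(motif))
    def hits(segment: str) -> int:
        h = brute_motif_count(segment, motif)
        if rc != motif:
            h += brute_motif_count(segment, rc)
        return h
    return (
        hits(seq[:terminal_window]) >= min_copies,
        hits(seq[-terminal_window:]) >= min_copies,
    )


def brute_union_length(intervals, region_start: int, region_end: int) -> int:
    """Bitmap union length of intervals clipped to [region_start, region_end)."""
    bitmap = np.zeros(region_end - region_start, dtype=bool)
    for s, e in intervals:
        s = max(s, region_start)
        e = min(e, region_end)
        if s < e:
            bitmap[s - region_start : e - region_start] = True
    return int(bitmap.sum())


def brute_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass covariance Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    if vx == 0 or vy == 0:
        return 0.0
    return cov / (vx**0.5 * vy**0.5)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def small_config() -> synthetic.SimulationConfig:
    """A fast, fully planted world: 2 pairs x 300 kb."""
    cfg = synthetic.SimulationConfig(
        n_chrom=2, chrom_len=300_000, telomere_copies=20, seed=7
    )
    cfg.gap_spec = [("chr1", 100_000, 100_300)]
    cfg.sv_spec = [
        synthetic.PlantedSV("INV", "chr1", 30_000, 35_000),
        synthetic.PlantedSV("INV", "chr2", 200_000, 208_000),
        synthetic.PlantedSV(
            "TRANS", "chr1", 150_000, 156_000,
            dest_chrom="chr2", dest_pos=50_000,
        ),
        synthetic.PlantedSV("DUP", "chr2", 120_000, 124_000),
    ]
    cfg.collapse_spec = [("chr1_h1", 50_000, 80_000, 2)]
    cfg.depth_window = 10_000
    cfg.sex_pair = (1, 6_000)  # chr2 hap2 is 6 kb (2%) longer
    return cfg


@pytest.fixture
def small_world(small_config):
    hap1, hap2, truth = synthetic.simulate_diploid_genome(small_config)
    return hap1, hap2, truth
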