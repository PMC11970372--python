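"""Synthetic diploid genomes, depth tracks, alignment blocks and expression
panels with planted ground truth.

Every downstream stage of the package gets its recovery test from here: the
generator plants telomere arrays, N-gaps, structural variants (>= 50 bp),
collapsed intervals (visible only in the depth track), one length-asymmetric
chromosome pair emulating a young ZW sex-chromosome pair, a coexpression
module mixing known-pathway and candidate-family genes, and sex-biased genes
inside the nonhomologous W region.  :class:`SyntheticTruth` records exactly
what was planted and serializes to JSON.

The default world is a toy-scale version of a phased conifer assembly
project: 4 chromosome pairs x 2 Mb (scaled from ~420 Mb chromosomes),
depth windows of 10 kb (scaled from the 100-kb windows used at full size),
mean HiFi depth 30x, a 40-sample expression panel with a module of 16
known-pathway plus 70 family genes, and a sex pair asymmetric by 1.7% of
the chromosome length (the magnitude seen on a real candidate ZW pair).
All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from haplotax._util import revcomp
from haplotax.io_formats import AlignmentBlock, DepthWindow, GenomeInterval

SVType = Literal["INV", "TRANS", "DUP", "INS", "DEL"]

TISSUES = ("root", "leaf", "bark", "flower")
SEXES = ("female", "male")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantedSV:
    """One planted structural variant, in haplotype-1 coordinates.

    chrom/start/end locate the source segment (degenerate start == end for
    novel insertions, where ``length`` gives the inserted size).  TRANS also
    carries the destination chromosome and insertion point.
    """

    sv_type: SVType
    chrom: str
    start: int
    end: int
    length: int = 0
    dest_chrom: str | None = None
    dest_pos: int | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in ("INV", "TRANS", "DUP", "INS", "DEL"):
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type == "INS":
            if self.length <= 0:
                raise ValueError("INS needs a positive length")
        else:
            if self.end <= self.start:
                raise ValueError("SV interval must be non-degenerate")
            object.__setattr__(self, "length", self.end - self.start)
        if self.sv_type == "TRANS" and (
            self.dest_chrom is None or self.dest_pos is None
        ):
            raise ValueError("TRANS needs dest_chrom and dest_pos")

    def to_dict(self) -> dict:
        return {
            "sv_type": self.sv_type,
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "length": self.length,
            "dest_chrom": self.dest_chrom,
            "dest_pos": self.dest_pos,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedSV":
        return cls(**d)


@dataclass(frozen=True)
class ExprSpec:
    """Shape of the synthetic expression panel.

    The defaults mirror a 40-sample multi-tissue panel in which 16 known
    biosynthesis-pathway genes co-express with 70 members of a candidate
    enzyme family (out of 158 family members genome-wide).
    """

    n_genes: int = 500
    n_samples: int = 40
    k_known: int = 16
    m_family: int = 70
    module_corr: float = 0.8
    noise_sd: float = 1.0
    n_family_extra: int = 88  # family members outside the module (158 total)

    def __post_init__(self) -> None:
        if not (0.0 < self.module_corr < 1.0):
            raise ValueError("module_corr must be in (0, 1)")
        if self.k_known + self.m_family > self.n_genes:
            raise ValueError("k_known + m_family must be <= n_genes")
        if (
            self.k_known + self.m_family + self.n_family_extra
            > self.n_genes
        ):
            raise ValueError("too many labelled genes for n_genes")


@dataclass
class SimulationConfig:
    n_chrom: int = 4
    chrom_len: int = 2_000_000
    telomere_motif: str = "TTTAGGG"
    telomere_copies: int = 100
    gap_spec: list[tuple[str, int, int]] | None = None
    sv_spec: list[PlantedSV] | None = None
    collapse_spec: list[tuple[str, int, int, int]] | None = None
    sex_pair: tuple[int, int] | None = None  # (pair index, extra bp on hap2)
    expr_spec: ExprSpec = field(default_factory=ExprSpec)
    mean_depth: float = 30.0
    depth_window: int = 10_000
    sequences: bool = True  # False -> coordinate-only mode (no FASTA strings)
    seed: int = 0

    @property
    def pair_ids(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def telomere_len(self) -> int:
        return len(self.telomere_motif) * self.telomere_copies


def default_config(seed: int = 0) -> SimulationConfig:
    """The stated toy world: 4 pairs x 2 Mb with a fixed planted feature set.

    chr2 carries no gaps (its haplotype-1 copy is the planted T2T
    chromosome); chr1<->chr3 carry an interchromosomal translocation (so the
    sex ranking must exclude them); chr4 is the sex pair, longer on
    haplotype 2 by 1.7% of the chromosome length.
    """
    cfg = SimulationConfig(seed=seed)
    L = cfg.chrom_len
    cfg.gap_spec = [
        ("chr1", int(0.30 * L), int(0.30 * L) + 500),
        ("chr1", int(0.80 * L), int(0.80 * L) + 800),
        ("chr3", int(0.55 * L), int(0.55 * L) + 500),
        ("chr4", int(0.40 * L), int(0.40 * L) + 600),
    ]
    cfg.sv_spec = [
        PlantedSV("INV", "chr1", int(0.10 * L), int(0.10 * L) + 10_000),
        PlantedSV("INV", "chr2", int(0.25 * L), int(0.25 * L) + 5_000),
        PlantedSV("INV", "chr3", int(0.70 * L), int(0.70 * L) + 8_000),
        PlantedSV("DUP", "chr2", int(0.60 * L), int(0.60 * L) + 4_000),
        PlantedSV("DUP", "chr4", int(0.75 * L), int(0.75 * L) + 6_000),
        PlantedSV(
            "TRANS", "chr1", int(0.50 * L), int(0.50 * L) + 12_000,
            dest_chrom="chr3", dest_pos=int(0.20 * L),
        ),
    ]
    w = cfg.depth_window
    cfg.collapse_spec = [
        ("chr1_h1", 40 * w, 43 * w, 3),
        ("chr3_h2", 100 * w, 105 * w, 2),
        ("chr2_h2", 150 * w, 152 * w, 2),
    ]
    cfg.sex_pair = (3, int(round(0.017 * L)))  # chr4, +1.7% on haplotype 2
    return cfg


@dataclass
class SyntheticTruth:
    """Exactly what the generators planted; the recovery-test oracle."""

    pair_ids: list[str]
    hap1_len: dict[str, int]
    hap2_len: dict[str, int]
    telomere_motif: str
    telomere_len: int
    gaps: list[tuple[str, int, int]]
    svs: list[PlantedSV]
    collapses: list[tuple[str, int, int, int]]
    sex_pair: str | None
    sex_extra_len: int = 0
    sex_region: tuple[str, int, int] | None = None  # W-chromosome coordinates
    depth_window: int = 10_000
    mean_depth: float = 30.0
    module_genes: list[str] = field(default_factory=list)
    known_genes: list[str] = field(default_factory=list)
    family_genes: list[str] = field(default_factory=list)
    sex_biased_genes: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def hap_chrom(self, pair: str, hap: int) -> str:
        return f"{pair}_h{hap}"

    def collapse_intervals(self) -> list[GenomeInterval]:
        return [GenomeInterval(c, s, e) for c, s, e, _ in self.collapses]

    def to_dict(self) -> dict:
        return {
            "pair_ids": self.pair_ids,
            "hap1_len": self.hap1_len,
            "hap2_len": self.hap2_len,
            "telomere_motif": self.telomere_motif,
            "telomere_len": self.telomere_len,
            "gaps": [list(g) for g in self.gaps],
            "svs": [sv.to_dict() for sv in self.svs],
            "collapses": [list(c) for c in self.collapses],
            "sex_pair": self.sex_pair,
            "sex_extra_len": self.sex_extra_len,
            "sex_region": list(self.sex_region) if self.sex_region else None,
            "depth_window": self.depth_window,
            "mean_depth": self.mean_depth,
            "module_genes": self.module_genes,
            "known_genes": self.known_genes,
            "family_genes": self.family_genes,
            "sex_biased_genes": [list(g) for g in self.sex_biased_genes],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            pair_ids=list(d["pair_ids"]),
            hap1_len={k: int(v) for k, v in d["hap1_len"].items()},
            hap2_len={k: int(v) for k, v in d["hap2_len"].items()},
            telomere_motif=d["telomere_motif"],
            telomere_len=int(d["telomere_len"]),
            gaps=[tuple(g) for g in d["gaps"]],
            svs=[PlantedSV.from_dict(s) for s in d["svs"]],
            collapses=[tuple(c) for c in d["collapses"]],
            sex_pair=d["sex_pair"],
            sex_extra_len=int(d["sex_extra_len"]),
            sex_region=tuple(d["sex_region"]) if d["sex_region"] else None,
            depth_window=int(d["depth_window"]),
            mean_depth=float(d["mean_depth"]),
            module_genes=list(d["module_genes"]),
            known_genes=list(d["known_genes"]),
            family_genes=list(d["family_genes"]),
            sex_biased_genes=[tuple(g) for g in d["sex_biased_genes"]],
            seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# genome simulation


def _validate_features(config: SimulationConfig) -> None:
    """Planted features must not overlap: ambiguous truth is refused."""
    margin = config.telomere_len
    by_chrom: dict[str, list[tuple[int, int, str]]] = {
        p: [] for p in config.pair_ids
    }
    for chrom, s, e in config.gap_spec or []:
        by_chrom[chrom].append((s, e, "gap"))
    for sv in config.sv_spec or []:
        if sv.sv_type == "INS":
            by_chrom[sv.chrom].append((sv.start, sv.start + 1, "INS"))
        else:
            by_chrom[sv.chrom].append((sv.start, sv.end, sv.sv_type))
        if sv.sv_type == "DUP":
            # tandem copy inserted at sv.end
            by_chrom[sv.chrom].append((sv.end, sv.end + 1, "DUP-site"))
        if sv.sv_type == "TRANS":
            by_chrom[sv.dest_chrom].append(
                (sv.dest_pos, sv.dest_pos + 1, "TRANS-dest")
            )
    for chrom, feats in by_chrom.items():
        feats.sort()
        for s, e, kind in feats:
            if s < margin or e > config.chrom_len - margin:
                raise ValueError(
                    f"planted {kind} on {chrom} [{s},{e}) intrudes into the "
                    f"telomere margin ({margin} bp)"
                )
        for (s1, e1, k1), (s2, e2, k2) in zip(feats, feats[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping planted features on {chrom}: "
                    f"{k1}[{s1},{e1}) vs {k2}[{s2},{e2})"
                )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


@dataclass(frozen=True)
class _Op:
    """One step of the haplotype-2 walk along haplotype-1 coordinates."""

    kind: str  # backbone | inv | skip | insert
    t_start: int = 0
    t_end: int = 0
    src_chrom: str | None = None  # for cross-chromosome inserts
    novel_len: int = 0  # for novel-sequence inserts


def _walk_ops(pair: str, config: SimulationConfig) -> list[_Op]:
    """Haplotype-2 construction plan for one chromosome, in hap1 order."""
    L = config.chrom_len
    interval_events: list[tuple[int, int, str]] = []  # on this chrom's hap1
    point_events: list[tuple[int, _Op]] = []

    for sv in config.sv_spec or []:
        if sv.chrom == pair:
            if sv.sv_type == "INV":
                interval_events.append((sv.start, sv.end, "inv"))
            elif sv.sv_type in ("TRANS", "DEL"):
                interval_events.append((sv.start, sv.end, "skip"))
            elif sv.sv_type == "DUP":
                point_events.append(
                    (
                        sv.end,
                        _Op("insert", sv.start, sv.end, src_chrom=pair),
                    )
                )
            elif sv.sv_type == "INS":
                point_events.append(
                    (sv.start, _Op("insert", novel_len=sv.length))
                )
        if sv.sv_type == "TRANS" and sv.dest_chrom == pair:
            point_events.append(
                (
                    sv.dest_pos,
                    _Op("insert", sv.start, sv.end, src_chrom=sv.chrom),
                )
            )
    if config.sex_pair is not None:
        idx, extra = config.sex_pair
        if config.pair_ids[idx] == pair and extra > 0:
            point_events.append(
                (config.telomere_len, _Op("insert", novel_len=extra))
            )

    events: list[tuple[int, int, str, _Op | None]] = [
        (s, e, kind, None) for s, e, kind in interval_events
    ] + [(p, p, "point", op) for p, op in point_events]
    events.sort(key=lambda t: (t[0], t[1]))

    ops: list[_Op] = []
    pos = 0
    for s, e, kind, payload in events:
        if s > pos:
            ops.append(_Op("backbone", pos, s))
        if kind == "point":
            ops.append(payload)
            pos = s
        else:
            ops.append(_Op(kind, s, e))
            pos = e
    if pos < L:
        ops.append(_Op("backbone", pos, L))
    return ops


def _hap2_len(pair: str, config: SimulationConfig) -> int:
    n = 0
    for op in _walk_ops(pair, config):
        if op.kind in ("backbone", "inv"):
            n += op.t_end - op.t_start
        elif op.kind == "insert":
            n += op.novel_len or (op.t_end - op.t_start)
    return n


def simulate_diploid_genome(
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], SyntheticTruth]:
    """Generate a haplotype pair with planted truth.

    Haplotype 1 is random sequence with telomere arrays at both ends and
    N-gaps at gap_spec positions.  Haplotype 2 is derived from haplotype 1
    by applying the planted SVs (inversions reverse-complemented in place,
    tandem duplications, cross-chromosome translocations, novel insertions,
    deletions) plus the sex-pair extra segment, a stretch of novel sequence
    just inside the left telomere of the W candidate.

    With ``config.sequences = False`` only coordinates are computed and the
    FASTA lists are empty (used for coordinate-level replicate tests).
    """
    if config.gap_spec is None and config.sv_spec is None:
        config = replace(config)  # tolerate a bare config: nothing planted
    _validate_features(config)
    rng = np.random.default_rng(config.seed)

    tel = config.telomere_motif * config.telomere_copies
    tel_rc = revcomp(tel)
    L = config.chrom_len

    hap1: list[tuple[str, str]] = []
    hap1_seqs: dict[str, str] = {}
    for pair in config.pair_ids:
        core = _random_seq(rng, L - 2 * len(tel)) if config.sequences else ""
        if config.sequences:
            seq = tel + core + tel_rc
            chars = list(seq)
            for chrom, s, e in config.gap_spec or []:
                if chrom == pair:
                    chars[s:e] = "N" * (e - s)
            seq = "".join(chars)
            hap1_seqs[pair] = seq
            hap1.append((f"{pair}_h1", seq))

    hap2: list[tuple[str, str]] = []
    hap2_len: dict[str, int] = {}
    for pair in config.pair_ids:
        ops = _walk_ops(pair, config)
        hap2_len[pair] = _hap2_len(pair, config)
        if not config.sequences:
            continue
        pieces: list[str] = []
        for op in ops:
            if op.kind == "backbone":
                pieces.append(hap1_seqs[pair][op.t_start : op.t_end])
            elif op.kind == "inv":
                pieces.append(revcomp(hap1_seqs[pair][op.t_start : op.t_end]))
            elif op.kind == "insert":
                if op.novel_len:
                    pieces.append(_random_seq(rng, op.novel_len))
                else:
                    pieces.append(
                        hap1_seqs[op.src_chrom][op.t_start : op.t_end]
                    )
            # skip: segment absent from hap2
        seq2 = "".join(pieces)
        assert len(seq2) == hap2_len[pair]
        hap2.append((f"{pair}_h2", seq2))

    sex_pair_id = None
    sex_extra = 0
    sex_region = None
    if config.sex_pair is not None:
        idx, extra = config.sex_pair
        sex_pair_id = config.pair_ids[idx]
        sex_extra = extra
        if extra > 0:
            sex_region = (
                f"{sex_pair_id}_h2",
                config.telomere_len,
                config.telomere_len + extra,
            )

    truth = SyntheticTruth(
        pair_ids=list(config.pair_ids),
        hap1_len={p: L for p in config.pair_ids},
        hap2_len=hap2_len,
        telomere_motif=config.telomere_motif,
        telomere_len=config.telomere_len,
        gaps=list(config.gap_spec or []),
        svs=list(config.sv_spec or []),
        collapses=list(config.collapse_spec or []),
        sex_pair=sex_pair_id,
        sex_extra_len=sex_extra,
        sex_region=sex_region,
        depth_window=config.depth_window,
        mean_depth=config.mean_depth,
        seed=config.seed,
    )
    return hap1, hap2, truth


# ---------------------------------------------------------------------------
# depth track


def simulate_depth_track(
    truth: SyntheticTruth,
    mean_depth: float | None = None,
    noise_sd: float = 3.0,
    window: int | None = None,
    seed: int = 0,
) -> list[DepthWindow]:
    """Windowed HiFi mapping depth over both haplotype assemblies.

    Non-collapsed windows draw from Normal(mean_depth, noise_sd) truncated
    at 0; windows contained in a planted collapsed interval of c copies draw
    from Normal(c * mean_depth, sqrt(c) * noise_sd).  The last window of a
    chromosome is truncated.
    """
    mean_depth = truth.mean_depth if mean_depth is None else mean_depth
    window = truth.depth_window if window is None else window
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    collapse = truth.collapse_intervals()
    copies_of = {
        (c, s, e): k for (c, s, e, k) in truth.collapses
    }

    out: list[DepthWindow] = []
    chrom_lens = {f"{p}_h1": truth.hap1_len[p] for p in truth.pair_ids}
    chrom_lens.update({f"{p}_h2": truth.hap2_len[p] for p in truth.pair_ids})
    for chrom in sorted(chrom_lens):
        L = chrom_lens[chrom]
        for start in range(0, L, window):
            end = min(start + window, L)
            c = 1
            for iv in collapse:
                if iv.chrom == chrom and iv.start <= start and end <= iv.end:
                    c = copies_of[(iv.chrom, iv.start, iv.end)]
                    break
            mu = c * mean_depth
            sd = math.sqrt(c) * noise_sd
            depth = mu + sd * rng.standard_normal() if sd > 0 else mu
            out.append(
                DepthWindow(GenomeInterval(chrom, start, end), max(0.0, depth))
            )
    return out


# ---------------------------------------------------------------------------
# alignment blocks


def simulate_alignment_blocks(
    truth: SyntheticTruth, min_block: int = 50
) -> list[AlignmentBlock]:
    """Deterministic projection of the planted truth into alignment space.

    Query is haplotype 2, target haplotype 1.  Collinear backbone segments
    become + strand blocks, each inversion one - strand block, each
    translocation one cross-chromosome block, and each duplication a second
    query block onto the same target interval.  Novel sequence (insertions,
    the sex-pair extra segment) is unaligned.  Blocks shorter than
    min_block are dropped.
    """
    cfg = _config_from_truth(truth)
    blocks: list[AlignmentBlock] = []
    for pair in truth.pair_ids:
        qchrom = f"{pair}_h2"
        qlen = truth.hap2_len[pair]
        qpos = 0
        for op in _walk_ops(pair, cfg):
            if op.kind == "backbone":
                n = op.t_end - op.t_start
                if n >= min_block:
                    blocks.append(
                        AlignmentBlock(
                            qchrom, qpos, qpos + n,
                            f"{pair}_h1", op.t_start, op.t_end,
                            "+", block_len=n, qlen=qlen,
                            tlen=truth.hap1_len[pair],
                        )
                    )
                qpos += n
            elif op.kind == "inv":
                n = op.t_end - op.t_start
                if n >= min_block:
                    blocks.append(
                        AlignmentBlock(
                            qchrom, qpos, qpos + n,
                            f"{pair}_h1", op.t_start, op.t_end,
                            "-", block_len=n, qlen=qlen,
                            tlen=truth.hap1_len[pair],
                        )
                    )
                qpos += n
            elif op.kind == "insert":
                if op.novel_len:
                    qpos += op.novel_len
                else:
                    n = op.t_end - op.t_start
                    if n >= min_block:
                        blocks.append(
                            AlignmentBlock(
                                qchrom, qpos, qpos + n,
                                f"{op.src_chrom}_h1", op.t_start, op.t_end,
                                "+", block_len=n, qlen=qlen,
                                tlen=truth.hap1_len[op.src_chrom],
                            )
                        )
                    qpos += n
            # skip ops consume target only
    return blocks


def _config_from_truth(truth: SyntheticTruth) -> SimulationConfig:
    """Rebuild the minimal config needed to replay the hap2 walk."""
    cfg = SimulationConfig(
        n_chrom=len(truth.pair_ids),
        chrom_len=max(truth.hap1_len.values()),
        sequences=False,
        seed=truth.seed,
        depth_window=truth.depth_window,
        mean_depth=truth.mean_depth,
    )
    cfg.gap_spec = list(truth.gaps)
    cfg.sv_spec = list(truth.svs)
    cfg.collapse_spec = list(truth.collapses)
    tel_len = truth.telomere_len
    if truth.telomere_motif:
        cfg.telomere_motif = truth.telomere_motif
        cfg.telomere_copies = tel_len // len(truth.telomere_motif)
    if truth.sex_pair is not None:
        cfg.sex_pair = (
            truth.pair_ids.index(truth.sex_pair),
            truth.sex_extra_len,
        )
    return cfg


# ---------------------------------------------------------------------------
# expression panel


def simulate_expression(
    expr_spec: ExprSpec, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, set[str]], list[str]]:
    """Expression panel with one planted coexpression module.

    Module genes (k_known pathway genes + m_family family genes) follow a
    one-factor model x_g = a * f + noise, with loading a chosen so that the
    pairwise correlation within the module is module_corr; all other genes
    are independent noise.  Values are exponentiated onto a non-negative
    TPM-like scale.  Returns (matrix, labels, module gene list) where labels
    has keys 'known_pathway' and 'family'; family members outside the module
    are the planted negatives for module-recovery tests.
    """
    spec = expr_spec
    rng = np.random.default_rng(seed)

    genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    samples = [f"s{j:02d}" for j in range(spec.n_samples)]

    n_module = spec.k_known + spec.m_family
    perm = rng.permutation(spec.n_genes)
    module_idx = np.sort(perm[:n_module])
    rest = perm[n_module:]
    known_idx = module_idx[: spec.k_known]
    family_in_idx = module_idx[spec.k_known :]
    family_out_idx = np.sort(rest[: spec.n_family_extra])

    rho, sd = spec.module_corr, spec.noise_sd
    loading = sd * math.sqrt(rho / (1.0 - rho))

    f = rng.standard_normal(spec.n_samples)
    x = sd * rng.standard_normal((spec.n_genes, spec.n_samples))
    x[module_idx, :] += loading * f
    base = rng.uniform(3.0, 8.0, size=spec.n_genes)
    values = np.power(2.0, base[:, None] + x)

    matrix = pd.DataFrame(values, index=genes, columns=samples)
    known = {genes[i] for i in known_idx}
    family = {genes[i] for i in family_in_idx} | {
        genes[i] for i in family_out_idx
    }
    labels = {"known_pathway": known, "family": family}
    module = [genes[i] for i in module_idx]
    return matrix, labels, module


# ---------------------------------------------------------------------------
# tissue x sex expression with planted sex-biased genes


def simulate_sex_expression(
    truth: SyntheticTruth,
    n_biased: int = 7,
    n_unbiased: int = 50,
    noise_sd: float = 0.0,
    on_level: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, tuple[str, int]], list[GenomeInterval]]:
    """Tissue x sex expression with sex-biased genes planted in the
    nonhomologous W region.

    Biased genes sit inside the sex region and are expressed in the flower
    of one sex only (5 female-biased, the remainder male-biased, matching a
    female-heterogametic ZW story); unbiased genes are expressed equally in
    both sexes, half of them inside the region, half outside.  Updates
    ``truth.sex_biased_genes`` in place and returns
    (expression, positions, regions).
    """
    if truth.sex_region is None:
        raise ValueError("truth has no nonhomologous sex region")
    rng = np.random.default_rng(seed)
    chrom, rs, re_ = truth.sex_region
    region = GenomeInterval(chrom, rs, re_)

    genes, positions, rows = [], {}, []
    biased: list[tuple[str, str]] = []
    columns = pd.MultiIndex.from_product(
        [TISSUES, SEXES], names=["tissue", "sex"]
    )

    def _row(on_sex: str | None) -> np.ndarray:
        vals = np.zeros(len(columns))
        for j, (tissue, sex) in enumerate(columns):
            if tissue == "flower":
                if on_sex is None or sex == on_sex:
                    vals[j] = on_level + noise_sd * rng.standard_normal()
            else:
                vals[j] = rng.uniform(0.5, 5.0)  # housekeeping background
        return np.clip(vals, 0.0, None)

    n_female = min(5, n_biased)
    for i in range(n_biased):
        g = f"sx{i:03d}"
        direction = "female" if i < n_female else "male"
        genes.append(g)
        positions[g] = (chrom, int(rng.integers(rs, re_)))
        rows.append(_row(direction))
        biased.append((g, f"{direction}-biased"))

    other_chrom = f"{truth.pair_ids[0]}_h1"
    for i in range(n_unbiased):
        g = f"bg{i:03d}"
        genes.append(g)
        if i % 2 == 0:
            positions[g] = (chrom, int(rng.integers(rs, re_)))
        else:
            positions[g] = (
                other_chrom,
                int(rng.integers(0, truth.hap1_len[truth.pair_ids[0]])),
            )
        rows.append(_row(None))

    expr = pd.DataFrame(rows, index=genes, columns=columns)
    truth.sex_biased_genes = biased
    return expr, positions, [region]


# ---------------------------------------------------------------------------
# clades and positions for the shortlist step


def simulate_clades_positions(
    genes: Sequence[str],
    chroms: Sequence[str],
    chrom_len: int,
    n_clades: int = 3,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, tuple[str, int]]]:
    """Assign genes to evolutionary clades and genomic positions.

    Clade sizes are deliberately unequal (geometric-ish split) so that
    clade-aware shortlisting has structure to exploit.
    """
    rng = np.random.default_rng(seed)
    clade_of: dict[str, str] = {}
    position_of: dict[str, tuple[str, int]] = {}
    weights = np.array([2.0 ** (-i) for i in range(n_clades)])
    weights /= weights.sum()
    for g in genes:
        c = int(rng.choice(n_clades, p=weights))
        clade_of[g] = f"clade{c + 1}"
        chrom = str(rng.choice(np.asarray(chroms, dtype=object)))
        position_of[g] = (chrom, int(rng.integers(0, chrom_len)))
    return clade_of, position_of


# ---------------------------------------------------------------------------
# randomized replicate worlds (used by the recovery test batteries)


def random_config(
    seed: int,
    n_chrom: int = 4,
    chrom_len: int = 2_000_000,
    sv_counts: dict[str, tuple[int, int]] | None = None,
    sv_len_range: tuple[int, int] = (500, 50_000),
    sequences: bool = False,
    sex_extra_frac: float = 0.017,
) -> SimulationConfig:
    """A randomized world: SV counts drawn per type, placed without overlap.

    sv_counts maps type -> (lo, hi) inclusive count range, default 3..20
    for INV/TRANS/DUP.  Placement keeps a margin inside telomeres and a
    separation of >= 200 bp between features so every planted feature is
    unambiguous.
    """
    sv_counts = sv_counts or {
        "INV": (3, 20), "TRANS": (3, 20), "DUP": (3, 20)
    }
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        n_chrom=n_chrom, chrom_len=chrom_len, sequences=sequences, seed=seed
    )
    margin = cfg.telomere_len + 1_000
    sep = 200

    # reserve space per chromosome with a simple rejection placement
    occupied: dict[str, list[tuple[int, int]]] = {
        p: [] for p in cfg.pair_ids
    }

    def _place(chrom: str, length: int) -> int | None:
        for _ in range(200):
            s = int(rng.integers(margin, chrom_len - margin - length))
            e = s + length
            if all(
                e + sep <= os or s >= oe + sep for os, oe in occupied[chrom]
            ):
                occupied[chrom].append((s, e))
                return s
        return None

    svs: list[PlantedSV] = []
    # exclude the last pair (the sex pair) from translocations so the
    # sex ranking's exclusion logic stays meaningful
    sex_idx = n_chrom - 1
    for sv_type, (lo, hi) in sv_counts.items():
        n = int(rng.integers(lo, hi + 1))
        for _ in range(n):
            length = int(rng.integers(sv_len_range[0], sv_len_range[1] + 1))
            if sv_type == "TRANS":
                src, dst = rng.choice(sex_idx, size=2, replace=False)
                src_chrom = cfg.pair_ids[int(src)]
                dst_chrom = cfg.pair_ids[int(dst)]
                s = _place(src_chrom, length)
                p = _place(dst_chrom, 1)
                if s is None or p is None:
                    continue
                svs.append(
                    PlantedSV("TRANS", src_chrom, s, s + length,
                              dest_chrom=dst_chrom, dest_pos=p)
                )
            else:
                chrom = cfg.pair_ids[int(rng.integers(0, n_chrom))]
                if sv_type == "DUP":
                    s = _place(chrom, length + 1)  # includes insert site
                else:
                    s = _place(chrom, length)
                if s is None:
                    continue
                if sv_type == "INS":
                    svs.append(PlantedSV("INS", chrom, s, s, length=length))
                else:
                    svs.append(PlantedSV(sv_type, chrom, s, s + length))
    cfg.sv_spec = svs
    cfg.gap_spec = []
    cfg.collapse_spec = []
    cfg.sex_pair = (sex_idx, int(round(sex_extra_frac * chrom_len)))
    return cfg


def random_collapse_spec(
    truth: SyntheticTruth,
    seed: int,
    n_calls: int = 6,
    min_windows: int = 3,
    max_windows: int = 8,
    copies: int = 2,
) -> list[tuple[str, int, int, int]]:
    """Plant window-aligned collapsed intervals on random haplotype chroms."""
    rng = np.random.default_rng(seed)
    w = truth.depth_window
    chroms = [f"{p}_h{h}" for p in truth.pair_ids for h in (1, 2)]
    lens = {f"{p}_h1": truth.hap1_len[p] for p in truth.pair_ids}
    lens.update({f"{p}_h2": truth.hap2_len[p] for p in truth.pair_ids})
    spec: list[tuple[str, int, int, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for _ in range(n_calls):
        for _try in range(100):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            n_win = int(rng.integers(min_windows, max_windows + 1))
            max_start_win = lens[chrom] // w - n_win - 1
            if max_start_win < 1:
                continue
            sw = int(rng.integers(1, max_start_win))
            s, e = sw * w, (sw + n_win) * w
            # keep one spacer window between calls so merging cannot join them
            if all(
                e + w <= os or s >= oe + w for os, oe in occupied[chrom]
            ):
                occupied[chrom].append((s, e))
                spec.append((chrom, s, e, copies))
                break
    return spec


__all__ = [
    "PlantedSV",
    "ExprSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "default_config",
    "simulate_diploid_genome",
    "simulate_depth_track",
    "simulate_alignment_blocks",
    "simulate_expression",
    "simulate_sex_expression",
    "simulate_clades_positions",
    "random_config",
    "random_collapse_spec",
    "TISSUES",
    "SEXES",
]
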