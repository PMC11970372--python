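"""End-to-end toy pipeline: simulate -> qc -> collapse -> sv -> mine -> sexscan.

:func:`run_all` drives every stage on a synthetic world with planted truth
and reports, alongside each stage's outputs, a set of recovery checks
(did the collapse caller find the planted collapses, did the SV classifier
recover the planted variants, did the module miner recover the planted
module, was the planted sex pair ranked first, were the planted sex-biased
genes found).  The report is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from haplotax import assembly_qc, collapse_depth, coexpr, hap_sv, sex_scan
from haplotax import synthetic
from haplotax.io_formats import (
    DepthWindow,
    GenomeInterval,
    write_depth_bed,
    write_fasta,
    write_paf,
    write_truth_json,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Per-stage parameter blocks with the documented defaults."""

    seed: int = 0
    simulation: synthetic.SimulationConfig | None = None
    # qc
    min_n_run: int = 10
    telomere_motif: str = assembly_qc.DEFAULT_TELOMERE_MOTIF
    terminal_window: int = 10_000
    min_copies: int = 10
    # collapse
    depth_noise_frac: float = 0.1  # noise_sd as a fraction of mean depth
    collapse_factor: float = 1.75
    # sv
    min_sv_len: int = 50
    # mine
    k_clusters: int | None = None
    n_target: int = 11
    # sexscan
    tau_on: float = 1.0
    tau_off: float = 0.1
    tissue: str = "flower"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from a plain dict; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = d.get("simulation")
        if isinstance(sim, dict):
            sim_known = {
                f.name for f in dataclasses.fields(synthetic.SimulationConfig)
            }
            bad = set(sim) - sim_known
            if bad:
                raise ValueError(f"unknown simulation keys: {sorted(bad)}")
            d = dict(d)
            d["simulation"] = synthetic.SimulationConfig(**sim)
        return cls(**d)


# ---------------------------------------------------------------------------
# recovery metrics (planted truth vs pipeline output)


def collapse_window_metrics(
    calls: Sequence[collapse_depth.CollapseCall],
    truth_intervals: Sequence[GenomeInterval],
    windows: Sequence[DepthWindow],
) -> tuple[float, float]:
    """Window-level (sensitivity, precision) of collapse calls."""
    call_ivs = [c.interval for c in calls]

    def _inside(w: DepthWindow, ivs: Sequence[GenomeInterval]) -> bool:
        return any(
            iv.chrom == w.interval.chrom
            and iv.start <= w.interval.start
            and w.interval.end <= iv.end
            for iv in ivs
        )

    tp = fp = fn = 0
    for w in windows:
        truthy = _inside(w, truth_intervals)
        called = _inside(w, call_ivs)
        if truthy and called:
            tp += 1
        elif called:
            fp += 1
        elif truthy:
            fn += 1
    sens = tp / (tp + fn) if tp + fn else 1.0
    prec = tp / (tp + fp) if tp + fp else 1.0
    return sens, prec


def sv_recovery_metrics(
    calls: Sequence[hap_sv.SVCall],
    truth: synthetic.SyntheticTruth,
    types: Sequence[str] = ("INV", "TRANS", "DUP"),
) -> dict[str, dict[str, float]]:
    """Per-type recall/precision of classified SVs against the planted set.

    INV/TRANS/DUP/DEL match on the exact target (haplotype-1) interval;
    INS (novel sequence, invisible on the target) matches on query
    chromosome and length.  An INS call over the planted sex-pair extra
    segment is expected, not a false positive, and is ignored.
    """
    sex_q = (
        GenomeInterval(*truth.sex_region) if truth.sex_region else None
    )
    out: dict[str, dict[str, float]] = {}
    for sv_type in types:
        planted = [sv for sv in truth.svs if sv.sv_type == sv_type]
        called = [c for c in calls if c.sv_type == sv_type]
        if sv_type == "INS" and sex_q is not None:
            called = [
                c
                for c in called
                if not (
                    c.q_interval is not None
                    and c.q_interval.chrom == sex_q.chrom
                    and c.q_interval.overlap_len(sex_q) > 0
                )
            ]

        def _matches(sv: synthetic.PlantedSV, c: hap_sv.SVCall) -> bool:
            if sv_type == "INS":
                return (
                    c.q_interval is not None
                    and c.q_interval.chrom == f"{sv.chrom}_h2"
                    and c.length == sv.length
                )
            return c.t_interval == GenomeInterval(
                f"{sv.chrom}_h1", sv.start, sv.end
            )

        matched_calls = set()
        tp = 0
        for sv in planted:
            for i, c in enumerate(called):
                if i not in matched_calls and _matches(sv, c):
                    matched_calls.add(i)
                    tp += 1
                    break
        recall = tp / len(planted) if planted else 1.0
        precision = tp / len(called) if called else 1.0
        out[sv_type] = {
            "recall": recall,
            "precision": precision,
            "n_planted": len(planted),
            "n_called": len(called),
        }
    return out


def module_recovery_metrics(
    module: coexpr.CoexpressionModule,
    labels: coexpr.GeneSetLabels,
    planted_module: Sequence[str],
) -> tuple[float, float]:
    """(recall, precision) of the selected module's family-gene candidates."""
    truth_fam = set(planted_module) & labels.family
    pred = set(module.candidates)
    if not truth_fam:
        return 1.0, 1.0
    tp = len(pred & truth_fam)
    recall = tp / len(truth_fam)
    precision = tp / len(pred) if pred else 1.0
    return recall, precision


# ---------------------------------------------------------------------------
# driver


def run_all(
    config: PipelineConfig | None = None, outdir: str | Path | None = None
) -> dict:
    """Run the full toy pipeline; return (and optionally write) the report.

    With outdir set, the synthetic inputs (FASTA pair, depth BED, PAF,
    truth JSON) and the per-stage tables are written there alongside
    report.json.  The same seed yields a byte-identical report.
    """
    config = config or PipelineConfig()
    sim = config.simulation or synthetic.default_config(config.seed)
    report: dict = {"seed": config.seed, "stages": {}, "checks": {}}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - stage naming contract
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrap

    # -- simulate ----------------------------------------------------------
    @_stage("simulate")
    def _sim():
        hap1, hap2, truth = synthetic.simulate_diploid_genome(sim)
        return hap1, hap2, truth

    hap1, hap2, truth = _sim
    if out is not None and hap1:
        write_fasta(out / "hap1.fasta", hap1)
        write_fasta(out / "hap2.fasta", hap2)
        write_truth_json(out / "truth.json", truth)

    # -- qc ----------------------------------------------------------------
    @_stage("qc")
    def _qc():
        records = []
        for hap_tag, records_in in (("h1", hap1), ("h2", hap2)):
            for name, seq in records_in:
                records.append(
                    assembly_qc.annotate_chromosome(
                        name,
                        seq,
                        haplotype=hap_tag,
                        min_n_run=config.min_n_run,
                        motif=config.telomere_motif,
                        terminal_window=config.terminal_window,
                        min_copies=config.min_copies,
                    )
                )
        table = [
            {
                "chrom": r.id,
                "length": r.length,
                "gaps": r.gap_count,
                "telomere_left": r.telomere_left,
                "telomere_right": r.telomere_right,
                "t2t": assembly_qc.t2t_status(r),
            }
            for r in records
        ]
        return records, table

    if hap1:
        records, qc_table = _qc
        report["stages"]["qc"] = qc_table
        planted_gaps = {}
        for chrom, s, e in truth.gaps:
            planted_gaps[f"{chrom}_h1"] = planted_gaps.get(f"{chrom}_h1", 0) + 1
        found_gaps = {r.id: r.gap_count for r in records if r.haplotype == "h1"}
        report["checks"]["qc_gap_counts"] = all(
            found_gaps.get(c, 0) == n for c, n in planted_gaps.items()
        )
        report["checks"]["qc_all_telomeres"] = all(
            r.telomere_left and r.telomere_right for r in records
        )
        gapless_h1 = [
            r.id
            for r in records
            if r.haplotype == "h1" and f"{r.id}" not in planted_gaps
        ]
        report["checks"]["qc_t2t_detected"] = all(
            assembly_qc.t2t_status(r)
            for r in records
            if r.id in gapless_h1
        )

    # -- collapse ----------------------------------------------------------
    @_stage("collapse")
    def _collapse():
        windows = synthetic.simulate_depth_track(
            truth,
            noise_sd=config.depth_noise_frac * truth.mean_depth,
            seed=config.seed + 1,
        )
        baseline = collapse_depth.modal_depth(windows)
        calls = collapse_depth.call_collapsed(
            windows, baseline, factor=config.collapse_factor
        )
        return windows, baseline, calls

    windows, baseline, calls = _collapse
    if out is not None:
        write_depth_bed(out / "depth.bed", windows)
    sens, prec = collapse_window_metrics(
        calls, truth.collapse_intervals(), windows
    )
    report["stages"]["collapse"] = {
        "baseline_depth": round(baseline, 3),
        "n_calls": len(calls),
        "sensitivity": sens,
        "precision": prec,
    }
    report["checks"]["collapse_recovery"] = sens >= 0.95 and prec >= 0.95

    # -- sv ----------------------------------------------------------------
    @_stage("sv")
    def _sv():
        blocks = synthetic.simulate_alignment_blocks(truth)
        chains = hap_sv.chain_syntenic(blocks, min_block=config.min_sv_len)
        svcalls = hap_sv.classify_svs(
            blocks, chains, min_sv_len=config.min_sv_len
        )
        return blocks, chains, svcalls

    blocks, chains, svcalls = _sv
    if out is not None:
        write_paf(out / "blocks.paf", blocks)
    sv_metrics = sv_recovery_metrics(svcalls, truth)
    report["stages"]["sv"] = {
        "counts": hap_sv.sv_type_counts(svcalls),
        "recovery": sv_metrics,
    }
    report["checks"]["sv_recovery"] = all(
        m["recall"] >= 0.95 and m["precision"] >= 0.95
        for m in sv_metrics.values()
    )

    # corrected lengths + sex ranking use both collapse and sv outputs
    @_stage("sex-ranking")
    def _rank():
        assembled = {
            p: (truth.hap1_len[p], truth.hap2_len[p]) for p in truth.pair_ids
        }
        extra_by_chrom = collapse_depth.extra_length_by_chrom(calls)
        extra = {
            p: (
                extra_by_chrom.get(f"{p}_h1", 0),
                extra_by_chrom.get(f"{p}_h2", 0),
            )
            for p in truth.pair_ids
        }
        rows = collapse_depth.corrected_lengths(assembled, extra)
        excluded = hap_sv.translocated_pairs(svcalls)
        ranking = collapse_depth.rank_sex_candidates(rows, excluded)
        return rows, excluded, ranking

    rows, excluded, ranking = _rank
    report["stages"]["sex_ranking"] = {
        "excluded_pairs": sorted(excluded),
        "top_candidate": ranking[0],
    }
    report["checks"]["sex_pair_recovered"] = (
        truth.sex_pair is not None
        and ranking[0]["pair_id"] == truth.sex_pair
    )

    # -- mine --------------------------------------------------------------
    @_stage("mine")
    def _mine():
        matrix, label_sets, module_genes = synthetic.simulate_expression(
            sim.expr_spec, seed=config.seed + 2
        )
        labels = coexpr.GeneSetLabels(**label_sets)
        module, corr, assignments = coexpr.mine_candidates(
            matrix, labels, k=config.k_clusters
        )
        clade_of, position_of = synthetic.simulate_clades_positions(
            module.candidates,
            [f"{p}_h1" for p in truth.pair_ids],
            max(truth.hap1_len.values()),
            seed=config.seed + 4,
        )
        shortlist = coexpr.shortlist_candidates(
            module.candidates, clade_of, position_of, config.n_target
        )
        truth.module_genes = module_genes
        truth.known_genes = sorted(label_sets["known_pathway"])
        truth.family_genes = sorted(label_sets["family"])
        return labels, module, module_genes, shortlist

    labels, module, module_genes, shortlist = _mine
    m_recall, m_prec = module_recovery_metrics(module, labels, module_genes)
    report["stages"]["mine"] = {
        "module_size": len(module.members),
        "n_known_in_module": module.n_known,
        "n_family_in_module": module.n_family,
        "recall": m_recall,
        "precision": m_prec,
        "shortlist": shortlist,
    }
    report["checks"]["module_recovery"] = m_recall >= 0.9 and m_prec >= 0.9

    # -- sexscan -----------------------------------------------------------
    @_stage("sexscan")
    def _sexscan():
        expr, positions, regions = synthetic.simulate_sex_expression(
            truth, seed=config.seed + 3
        )
        found = sex_scan.sex_biased_genes(
            expr,
            regions,
            positions,
            tau_on=config.tau_on,
            tau_off=config.tau_off,
            tissue=config.tissue,
        )
        return found

    found = _sexscan
    planted_bias = {g for g, _ in truth.sex_biased_genes}
    found_set = {c.gene for c in found}
    report["stages"]["sexscan"] = {
        "n_planted": len(planted_bias),
        "n_found": len(found_set),
        "genes": sorted(found_set),
    }
    report["checks"]["sexscan_exact"] = found_set == planted_bias and all(
        dict(truth.sex_biased_genes)[c.gene] == c.direction for c in found
    )

    report["all_checks_pass"] = all(report["checks"].values())
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report


__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_all",
    "collapse_window_metrics",
    "sv_recovery_metrics",
    "module_recovery_metrics",
]
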