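"""Assembly accounting on a small synthetic haplotype pair.

Builds a 4-pair diploid toy genome with planted gaps and telomeres, then
reports per-chromosome gap counts, telomere status and T2T completeness,
plus assembly-level NX values and the QV-to-error-rate conversion.
"""

from haplotax import assembly_qc as qc
from haplotax import synthetic

hap1, hap2, truth = synthetic.simulate_diploid_genome(synthetic.default_config(seed=1))

records = [qc.annotate_chromosome(name, seq, haplotype="h1") for name, seq in hap1]
print("chrom        len(bp)  gaps  telomeres  T2T")
for r in records:
    tel = f"{'L' if r.telomere_left else '-'}{'R' if r.telomere_right else '-'}"
    print(f"{r.id:10s} {r.length:9d}  {r.gap_count:4d}  {tel:^9s}  {qc.t2t_status(r)}")

stats = qc.assembly_stats(records)
print(f"\nhaplotype-1 total: {stats.total_len:,} bp, {stats.gap_count} gaps")
print(f"contig N50 (gaps break contigs): {stats.n50:,} bp")
print("NX curve:", {x: f"{v:,}" for x, v in sorted(stats.contig_n_values.items())})

# a Phred-scaled consensus QV of 60 means 1 expected base error per Mbp
for qv in (60.0, 59.5658, 30.0):
    print(f"QV {qv:7.4f} -> {qc.qv_to_errors_per_mbp(qv):8.2f} errors/Mbp")

# anchoring rate: fraction of assembled sequence placed on chromosomes
print("anchoring rate (toy, all anchored):",
      qc.anchoring_rate(stats.anchored_len, stats.total_len), "%")
# A chromosome is telomere-to-telomere (T2T) when both telomeres are present
# and it contains zero gaps; chr2_h1 above is the planted T2T case.
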