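"""Haplotype-to-haplotype SV classification from alignment blocks.

Plants inversions, a translocation and duplications in a toy diploid
genome, projects them into PAF-style alignment blocks, and classifies the
blocks back into typed SV calls against the syntenic backbone.
"""

from haplotax import hap_sv, synthetic
from haplotax.io_formats import GenomeInterval

cfg = synthetic.default_config(seed=1)
_, _, truth = synthetic.simulate_diploid_genome(cfg)
blocks = synthetic.simulate_alignment_blocks(truth)
print(f"{len(blocks)} alignment blocks (query = haplotype 2, target = haplotype 1)")

chains = hap_sv.chain_syntenic(blocks)
calls = hap_sv.classify_svs(blocks, chains)
print("SV calls (>= 50 bp):", hap_sv.sv_type_counts(calls))
planted = {}
for sv in truth.svs:
    planted[sv.sv_type] = planted.get(sv.sv_type, 0) + 1
print("planted truth:      ", planted)

genome_len = sum(truth.hap1_len.values()) + sum(truth.hap2_len.values())
print(f"SVs cover {hap_sv.sv_genome_fraction(calls, genome_len)} % of the genome")

# unaligned (nonhomologous) fraction of the W-specific region
chrom, s, e = truth.sex_region
region = GenomeInterval(chrom, 0, e + 50_000)
unaligned, pct = hap_sv.unaligned_fraction(region, blocks)
print(f"\nW-chromosome head {region.chrom}:0-{region.end:,}: "
      f"{unaligned:,} bp unaligned ({pct} %) — the nonhomologous region "
      "where sex-determination genes are expected")
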