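import numpy as np
import pytest

from conftest import brute_union_length
from haplotax import hap_sv, synthetic
from haplotax.io_formats import AlignmentBlock, GenomeInterval
from haplotax.pipeline import sv_recovery_metrics


def _block(qs, qe, ts, te, strand="+", q="chr1_h2", t="chr1_h1"):
    return AlignmentBlock(q, qs, qe, t, ts, te, strand, block_len=qe - qs)


class TestChaining:
    def test_single_block_chained(self):
        b = _block(0, 1000, 0, 1000)
        chains = hap_sv.chain_syntenic([b])
        assert chains.chains[("chr1_h2", "chr1_h1")] == [b]
        assert chains.partner["chr1_h2"] == "chr1_h1"

    def test_crossing_order_keeps_longer(self):
        # two + blocks whose target order crosses: LIS keeps the longer one
        long = _block(0, 5000, 6000, 11000)
        short = _block(6000, 7000, 0, 1000)
        chains = hap_sv.chain_syntenic([long, short])
        assert chains.chains[("chr1_h2", "chr1_h1")] == [long]

    def test_deterministic_under_permutation(self):
        rng = np.random.default_rng(0)
        blocks = [
            _block(i * 1000, i * 1000 + 800, i * 1000, i * 1000 + 800)
            for i in range(10)
        ]
        shuffled = list(blocks)
        rng.shuffle(shuffled)
        a = hap_sv.chain_syntenic(blocks)
        b = hap_sv.chain_syntenic(shuffled)
        assert a.chains == b.chains


class TestClassification:
    def test_collinear_blocks_no_calls(self):
        blocks = [
            _block(0, 1000, 0, 1000),
            _block(1000, 2000, 1000, 2000),
        ]
        assert hap_sv.classify_svs(blocks) == []

    def test_closed_loop_with_planted_truth(self, small_world):
        _, _, truth = small_world
        blocks = synthetic.simulate_alignment_blocks(truth)
        calls = hap_sv.classify_svs(blocks)
        metrics = sv_recovery_metrics(calls, truth)
        for sv_type, m in metrics.items():
            assert m["recall"] == 1.0, (sv_type, m)
            assert m["precision"] == 1.0, (sv_type, m)
        # exact coordinate recovery of an inversion
        inv_calls = {
            (c.t_interval.chrom, c.t_interval.start, c.t_interval.end)
            for c in calls
            if c.sv_type == "INV"
        }
        assert ("chr1_h1", 30_000, 35_000) in inv_calls

    def test_small_inversion_below_threshold_dropped(self):
        blocks = [
            _block(0, 1000, 0, 1000),
            _block(1000, 1040, 1000, 1040, strand="-"),
            _block(1040, 2000, 1040, 2000),
        ]
        calls = hap_sv.classify_svs(blocks, min_sv_len=50)
        assert calls == []

    def test_inversion_at_exact_threshold_kept(self):
        blocks = [
            _block(0, 1000, 0, 1000),
            _block(1000, 1050, 1000, 1050, strand="-"),
            _block(1050, 2000, 1050, 2000),
        ]
        calls = hap_sv.classify_svs(blocks, min_sv_len=50)
        assert [c.sv_type for c in calls] == ["INV"]

    def test_order_invariance(self, small_world):
        _, _, truth = small_world
        blocks = synthetic.simulate_alignment_blocks(truth)
        rng = np.random.default_rng(3)
        shuffled = list(blocks)
        rng.shuffle(shuffled)
        a = hap_sv.classify_svs(blocks)
        b = hap_sv.classify_svs(shuffled)
        assert a == b

    def test_one_sided_gaps_become_ins_del(self):
        # query gap only -> INS; target gap only -> DEL
        blocks = [
            _block(0, 1000, 0, 1000),
            _block(1500, 2500, 1000, 2000),  # 500 bp query-only gap
            _block(2500, 3500, 2600, 3600),  # 600 bp target-only gap
        ]
        calls = hap_sv.classify_svs(blocks)
        types = sorted(c.sv_type for c in calls)
        assert types == ["DEL", "INS"]
        ins = next(c for c in calls if c.sv_type == "INS")
        assert (ins.q_interval.start, ins.q_interval.end) == (1000, 1500)
        dele = next(c for c in calls if c.sv_type == "DEL")
        assert (dele.t_interval.start, dele.t_interval.end) == (2000, 2600)


class TestUnalignedFraction:
    def test_full_coverage(self):
        region = GenomeInterval("chr12_h2", 0, 1000)
        blocks = [_block(0, 1000, 0, 1000, q="chr12_h2")]
        assert hap_sv.unaligned_fraction(region, blocks) == (0, 0.0)

    def test_partial_coverage_percent(self):
        region = GenomeInterval("w", 0, 30_000_000)
        blocks = [_block(0, 20_000_000, 0, 20_000_000, q="w")]
        unaligned, pct = hap_sv.unaligned_fraction(region, blocks)
        assert unaligned == 10_000_000
        assert pct == 33.3

    def test_overlapping_blocks_counted_once(self):
        region = GenomeInterval("w", 0, 1000)
        blocks = [
            _block(0, 600, 0, 600, q="w"),
            _block(400, 800, 400, 800, q="w"),
        ]
        unaligned, pct = hap_sv.unaligned_fraction(region, blocks)
        assert unaligned == 200
        assert pct == 20.0

    def test_matches_bitmap_oracle_on_random_regions(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            region_len = int(rng.integers(1_000, 100_000))
            region = GenomeInterval("w", 0, region_len)
            ivs = []
            blocks = []
            for _ in range(int(rng.integers(0, 15))):
                s = int(rng.integers(0, region_len - 10))
                e = int(rng.integers(s + 1, min(region_len, s + 5_000) + 1))
                ivs.append((s, e))
                blocks.append(_block(s, e, s, e, q="w"))
            unaligned, _ = hap_sv.unaligned_fraction(region, blocks)
            want = region_len - brute_union_length(ivs, 0, region_len)
            assert unaligned == want


class TestGenomeFraction:
    def test_no_calls(self):
        assert hap_sv.sv_genome_fraction([], 1000) == 0.0

    def test_direct_arithmetic(self):
        call = hap_sv.SVCall(
            "INV", GenomeInterval("q", 0, 134), GenomeInterval("t", 0, 134), 134
        )
        assert hap_sv.sv_genome_fraction([call], 1000) == 13.4

    def test_equals_sum_of_per_type_fractions(self, small_world):
        _, _, truth = small_world
        blocks = synthetic.simulate_alignment_blocks(truth)
        calls = hap_sv.classify_svs(blocks)
        genome = sum(truth.hap1_len.values()) + sum(truth.hap2_len.values())
        total_bp = sum(c.length for c in calls)
        per_type_bp = sum(
            sum(c.length for c in calls if c.sv_type == t)
            for t in {"INV", "TRANS", "DUP", "INS", "DEL"}
        )
        assert total_bp == per_type_bp
        assert hap_sv.sv_genome_fraction(calls, genome) == pytest.approx(
            round(100 * total_bp / genome, 1), abs=0.05
        )


def test_translocated_pairs_naming(small_world):
    _, _, truth = small_world
    blocks = synthetic.simulate_alignment_blocks(truth)
    calls = hap_sv.classify_svs(blocks)
    pairs = hap_sv.translocated_pairs(calls)
    assert pairs == {"chr1", "chr2"}  # planted chr1 -> chr2 translocation
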