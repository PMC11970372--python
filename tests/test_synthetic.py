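import numpy as np
import pytest

from haplotax import synthetic
from haplotax._util import revcomp
from haplotax.synthetic import (
    ExprSpec,
    PlantedSV,
    SimulationConfig,
    simulate_alignment_blocks,
    simulate_depth_track,
    simulate_diploid_genome,
    simulate_expression,
)


def _bare_config(**kw) -> SimulationConfig:
    cfg = SimulationConfig(
        n_chrom=2, chrom_len=100_000, telomere_copies=20, seed=3, **kw
    )
    cfg.gap_spec = []
    cfg.sv_spec = []
    cfg.collapse_spec = []
    cfg.sex_pair = None
    return cfg


class TestDiploidGenome:
    def test_no_svs_haplotypes_identical(self):
        hap1, hap2, truth = simulate_diploid_genome(_bare_config())
        assert [s for _, s in hap1] == [s for _, s in hap2]
        assert truth.hap1_len == truth.hap2_len

    def test_sex_extra_only_difference(self):
        cfg = _bare_config()
        cfg.sex_pair = (1, 5_000)
        hap1, hap2, truth = simulate_diploid_genome(cfg)
        assert hap1[0][1] == hap2[0][1]  # chr1 untouched
        assert len(hap2[1][1]) == len(hap1[1][1]) + 5_000
        # the extra sits just inside the left telomere; flanks are conserved
        tel = truth.telomere_len
        assert hap2[1][1][:tel] == hap1[1][1][:tel]
        assert hap2[1][1][tel + 5_000 :] == hap1[1][1][tel:]

    def test_inversion_is_reverse_complement(self):
        cfg = _bare_config()
        cfg.sv_spec = [PlantedSV("INV", "chr1", 30_000, 35_000)]
        hap1, hap2, truth = simulate_diploid_genome(cfg)
        s1 = hap1[0][1]
        s2 = hap2[0][1]
        # single inversion leaves coordinates aligned
        assert s2[30_000:35_000] == revcomp(s1[30_000:35_000])
        assert s2[:30_000] == s1[:30_000]
        assert s2[35_000:] == s1[35_000:]

    def test_gaps_are_n_runs(self):
        cfg = _bare_config()
        cfg.gap_spec = [("chr1", 40_000, 40_500)]
        hap1, _, _ = simulate_diploid_genome(cfg)
        assert hap1[0][1][40_000:40_500] == "N" * 500
        assert hap1[0][1][39_999] != "N"

    def test_telomeres_planted_both_ends(self):
        cfg = _bare_config()
        hap1, _, truth = simulate_diploid_genome(cfg)
        motif = cfg.telomere_motif
        assert hap1[0][1].startswith(motif * cfg.telomere_copies)
        assert hap1[0][1].endswith(revcomp(motif * cfg.telomere_copies))

    def test_same_seed_bit_identical(self):
        cfg = _bare_config()
        cfg.sv_spec = [PlantedSV("DUP", "chr2", 50_000, 54_000)]
        a = simulate_diploid_genome(cfg)
        b = simulate_diploid_genome(cfg)
        assert a[0] == b[0] and a[1] == b[1]

    def test_overlapping_svs_rejected(self):
        cfg = _bare_config()
        cfg.sv_spec = [
            PlantedSV("INV", "chr1", 30_000, 40_000),
            PlantedSV("DUP", "chr1", 35_000, 45_000),
        ]
        with pytest.raises(ValueError, match="overlap"):
            simulate_diploid_genome(cfg)

    def test_deletion_and_insertion_lengths(self):
        cfg = _bare_config()
        cfg.sv_spec = [
            PlantedSV("DEL", "chr1", 30_000, 33_000),
            PlantedSV("INS", "chr2", 60_000, 60_000, length=2_000),
        ]
        _, _, truth = simulate_diploid_genome(cfg)
        assert truth.hap2_len["chr1"] == 100_000 - 3_000
        assert truth.hap2_len["chr2"] == 100_000 + 2_000


class TestDepthTrack:
    def test_zero_noise_exact_baseline(self):
        _, _, truth = simulate_diploid_genome(_bare_config())
        windows = simulate_depth_track(truth, mean_depth=30, noise_sd=0.0)
        assert all(w.mean_depth == 30.0 for w in windows)

    def test_zero_noise_collapse_doubles(self):
        cfg = _bare_config()
        cfg.collapse_spec = [("chr1_h1", 20_000, 40_000, 2)]
        _, _, truth = simulate_diploid_genome(cfg)
        windows = simulate_depth_track(truth, mean_depth=30, noise_sd=0.0)
        for w in windows:
            inside = (
                w.interval.chrom == "chr1_h1"
                and 20_000 <= w.interval.start
                and w.interval.end <= 40_000
            )
            assert w.mean_depth == (60.0 if inside else 30.0)

    def test_empirical_mean_within_3_se(self):
        cfg = _bare_config()
        cfg.chrom_len = 3_000_000  # 300 windows x 2 chrom x 2 haps = 1200
        _, _, truth = simulate_diploid_genome(
            SimulationConfig(
                n_chrom=2, chrom_len=3_000_000, telomere_copies=20,
                seed=5, sequences=False,
            )
        )
        windows = simulate_depth_track(truth, mean_depth=30, noise_sd=3.0, seed=11)
        depths = np.array([w.mean_depth for w in windows])
        assert len(depths) >= 1000
        se = 3.0 / np.sqrt(len(depths))
        assert abs(depths.mean() - 30.0) < 3 * se

    def test_nonpositive_mean_depth_rejected(self):
        _, _, truth = simulate_diploid_genome(_bare_config())
        with pytest.raises(ValueError):
            simulate_depth_track(truth, mean_depth=0.0)


class TestAlignmentBlocks:
    def test_no_svs_one_block_per_pair(self):
        _, _, truth = simulate_diploid_genome(_bare_config())
        blocks = simulate_alignment_blocks(truth)
        assert len(blocks) == 2
        assert all(b.strand == "+" for b in blocks)
        assert all(b.qstart == 0 and b.qend == 100_000 for b in blocks)

    def test_single_inversion_block(self):
        cfg = _bare_config()
        cfg.sv_spec = [PlantedSV("INV", "chr1", 30_000, 35_000)]
        _, _, truth = simulate_diploid_genome(cfg)
        minus = [
            b for b in simulate_alignment_blocks(truth) if b.strand == "-"
        ]
        assert len(minus) == 1
        b = minus[0]
        assert (b.tchrom, b.tstart, b.tend) == ("chr1_h1", 30_000, 35_000)
        assert (b.qchrom, b.qstart, b.qend) == ("chr1_h2", 30_000, 35_000)

    def test_duplication_two_query_blocks_one_target(self):
        cfg = _bare_config()
        cfg.sv_spec = [PlantedSV("DUP", "chr2", 50_000, 54_000)]
        _, _, truth = simulate_diploid_genome(cfg)
        blocks = simulate_alignment_blocks(truth)
        covering = [
            b
            for b in blocks
            if b.tchrom == "chr2_h1" and b.tstart < 50_000 and b.tend >= 54_000
        ]
        extra = [
            b
            for b in blocks
            if (b.tstart, b.tend) == (50_000, 54_000)
        ]
        assert len(covering) == 1 and len(extra) == 1

    def test_min_block_respected(self):
        _, _, truth = simulate_diploid_genome(_bare_config())
        assert all(
            b.qend - b.qstart >= 50 for b in simulate_alignment_blocks(truth)
        )


class TestExpression:
    def test_degenerate_limit_high_correlation(self):
        spec = ExprSpec(
            n_genes=60, n_samples=40, k_known=5, m_family=10,
            module_corr=0.999, noise_sd=1.0, n_family_extra=10,
        )
        matrix, labels, module = simulate_expression(spec, seed=0)
        import haplotax.coexpr as cx

        norm = cx.normalize_expression(matrix)
        corr = cx.correlation_matrix(norm, module)
        vals = corr.to_numpy()
        off = vals[np.triu_indices_from(vals, k=1)]
        assert off.min() >= 0.99

    def test_off_module_near_null_correlation(self):
        # null Pearson r at n=40 has E|r| = sqrt(2/(pi*39)) ~ 0.128,
        # so the mean absolute off-module correlation must sit near that,
        # comfortably below 0.15
        spec = ExprSpec()
        matrix, labels, module = simulate_expression(spec, seed=1)
        import haplotax.coexpr as cx

        norm = cx.normalize_expression(matrix)
        background = [g for g in matrix.index if g not in set(module)][:80]
        corr = cx.correlation_matrix(norm, background)
        vals = corr.to_numpy()
        off = np.abs(vals[np.triu_indices_from(vals, k=1)])
        assert off.mean() < 0.15

    def test_same_seed_identical(self):
        spec = ExprSpec()
        a, _, _ = simulate_expression(spec, seed=9)
        b, _, _ = simulate_expression(spec, seed=9)
        assert a.equals(b)

    def test_module_corr_bounds_rejected(self):
        with pytest.raises(ValueError):
            ExprSpec(module_corr=1.0)
        with pytest.raises(ValueError):
            ExprSpec(module_corr=0.0)

    def test_labels_partition(self):
        spec = ExprSpec()
        matrix, labels, module = simulate_expression(spec, seed=2)
        known = labels["known_pathway"]
        family = labels["family"]
        assert known <= set(module)
        assert len(known) == spec.k_known
        assert len(family & set(module)) == spec.m_family
        assert len(family) == spec.m_family + spec.n_family_extra
        assert not (known & family)


class TestSexExpression:
    def test_planted_bias_recorded(self, small_world):
        _, _, truth = small_world
        expr, positions, regions = synthetic.simulate_sex_expression(
            truth, n_biased=7, n_unbiased=50, seed=0
        )
        assert len(truth.sex_biased_genes) == 7
        assert expr.shape == (57, 8)
        region = regions[0]
        for gene, _direction in truth.sex_biased_genes:
            chrom, pos = positions[gene]
            assert region.contains_point(chrom, pos)


def test_random_config_counts_within_ranges():
    cfg = synthetic.random_config(42, sv_counts={"INV": (3, 20), "DUP": (3, 20)})
    counts = {}
    for sv in cfg.sv_spec:
        counts[sv.sv_type] = counts.get(sv.sv_type, 0) + 1
    assert set(counts) == {"INV", "DUP"}
    assert all(3 <= n <= 20 for n in counts.values())
    # placement leaves planted features valid
    synthetic.simulate_diploid_genome(cfg)
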