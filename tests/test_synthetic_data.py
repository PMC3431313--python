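import numpy as np
import pandas as pd
import pytest

from h1blocks.errors import ConfigurationError, SizingError
from h1blocks.family_analysis import detect_clusters
from h1blocks.synthetic_data import (BlockTruth, SimConfig, generate_genome,
                                     oracle_peak_set, plant_blocks,
                                     simulate_expression,
                                     simulate_window_counts)


class TestSimConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(n_genes=-1), dict(fraction_clustered=1.5),
        dict(block_enrichment=0.9), dict(background_rate=0),
        dict(derepressed_fraction=-0.1), dict(repression_strength=-1),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)

    def test_family_sizes_length_checked(self):
        cfg = SimConfig(n_families=3, family_sizes=(5, 5))
        with pytest.raises(ConfigurationError):
            cfg.sizes_list()


class TestGenerateGenome:
    def test_empty_gene_list(self):
        cfg = SimConfig(n_genes=0, n_families=1, family_sizes=0)
        ann = generate_genome(cfg)
        assert ann.n_genes == 0
        assert len(ann.chrom_sizes) == cfg.n_chroms

    def test_fully_clustered_single_family(self):
        cfg = SimConfig(n_chroms=1, chrom_length=200_000, n_genes=5,
                        n_families=1, family_sizes=5, fraction_clustered=1.0)
        ann = generate_genome(cfg)
        cs = detect_clusters(ann)
        assert len(cs) == 1
        assert cs.clusters.iloc[0]["n_genes"] == 5

    def test_genes_non_overlapping_and_sorted(self, default_config):
        ann = generate_genome(default_config)
        for chrom in ann.chrom_sizes:
            g = ann.genes_on(chrom)
            assert (g["start"].diff().dropna() > 0).all()
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_determinism_byte_identical(self):
        a = generate_genome(SimConfig(seed=7))
        b = generate_genome(SimConfig(seed=7))
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_different_seeds_differ(self):
        a = generate_genome(SimConfig(seed=1))
        b = generate_genome(SimConfig(seed=2))
        assert not a.genes.equals(b.genes)

    def test_clustered_fraction_realized(self, default_config):
        ann = generate_genome(default_config)
        clustered = detect_clusters(ann).gene_ids()
        n_family = ann.genes["family_id"].notna().sum()
        assert abs(len(clustered) / n_family - default_config.fraction_clustered) < 0.1

    def test_sizing_error_names_constraint(self):
        cfg = SimConfig(n_chroms=1, chrom_length=50_000, n_genes=100,
                        n_families=1, family_sizes=3)
        with pytest.raises(SizingError, match="chrom_length"):
            generate_genome(cfg)


class TestPlantBlocks:
    def test_zero_blocks(self, three_gene_cluster):
        cfg = SimConfig(seed=0, n_intergenic_blocks=0)
        truth = plant_blocks(three_gene_cluster, cfg, over_clusters=False)
        assert len(truth) == 0

    def test_cluster_block_flank_arithmetic(self, three_gene_cluster):
        cfg = SimConfig(seed=0, n_intergenic_blocks=0)
        truth = plant_blocks(three_gene_cluster, cfg)
        row = truth.intervals.iloc[0]
        assert (row["start"], row["end"]) == (7_000, 28_000)
        assert row["covered_families"] == ("famA",)

    def test_intergenic_block_far_from_genes(self):
        cfg = SimConfig(seed=3, n_intergenic_blocks=2, intergenic_block_length=5_000)
        ann = generate_genome(cfg)
        truth = plant_blocks(ann, cfg, over_clusters=False)
        assert len(truth) == 2
        # brute-force distance scan against every gene interval
        for row in truth.intervals.itertuples():
            for gene in ann.genes_on(row.chrom).itertuples():
                gap = max(gene.start - row.end, row.start - gene.end)
                assert gap >= cfg.flank

    def test_no_clusters_raises_configuration_error(self):
        cfg = SimConfig(n_chroms=1, chrom_length=500_000, n_genes=20,
                        n_families=2, family_sizes=3, fraction_clustered=0.0)
        ann = generate_genome(cfg)
        with pytest.raises(ConfigurationError, match="cluster"):
            plant_blocks(ann, cfg)

    def test_blocks_non_overlapping(self, default_config):
        ann = generate_genome(default_config)
        truth = plant_blocks(ann, default_config)
        for chrom, grp in truth.intervals.groupby("chrom"):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()


class TestSimulateWindowCounts:
    def test_null_construction_means_match(self):
        cfg = SimConfig(n_chroms=1, chrom_length=10_000_000, n_genes=0,
                        n_families=1, family_sizes=0, seed=5)
        ann = generate_genome(cfg)
        counts = simulate_window_counts(ann, BlockTruth(), cfg)
        k, m = counts.chip["chr1"], counts.input["chr1"]
        se = np.sqrt(k.var() / len(k) + m.var() / len(m))
        assert abs(k.mean() - m.mean()) < 3 * se
        assert len(k) >= 10 ** 5

    def test_block_interior_mean_matches_fold(self):
        cfg = SimConfig(n_chroms=1, chrom_length=2_000_000, n_genes=0,
                        n_families=1, family_sizes=0, seed=6,
                        block_enrichment=4.0, background_rate=5.0)
        ann = generate_genome(cfg)
        truth = BlockTruth(pd.DataFrame(
            [("chr1", 100_000, 600_000, 4.0, ())],
            columns=["chrom", "start", "end", "enrichment", "covered_families"]))
        counts = simulate_window_counts(ann, truth, cfg)
        inside = counts.chip["chr1"][1_000:6_000]
        se = inside.std() / np.sqrt(len(inside))
        assert abs(inside.mean() - 20.0) < 3 * se

    def test_determinism(self, default_config):
        ann = generate_genome(default_config)
        truth = plant_blocks(ann, default_config)
        a = simulate_window_counts(ann, truth, default_config)
        b = simulate_window_counts(ann, truth, default_config)
        for chrom in a.chroms:
            np.testing.assert_array_equal(a.chip[chrom], b.chip[chrom])
            np.testing.assert_array_equal(a.input[chrom], b.input[chrom])

    def test_stream_independence_from_expression_params(self):
        ann1 = generate_genome(SimConfig(seed=9))
        cfg2 = SimConfig(seed=9, repression_strength=0.1, expression_noise_sd=0.01)
        ann2 = generate_genome(cfg2)
        pd.testing.assert_frame_equal(ann1.genes, ann2.genes)
        t1 = plant_blocks(ann1, SimConfig(seed=9))
        t2 = plant_blocks(ann2, cfg2)
        c1 = simulate_window_counts(ann1, t1, SimConfig(seed=9))
        c2 = simulate_window_counts(ann2, t2, cfg2)
        for chrom in c1.chroms:
            np.testing.assert_array_equal(c1.chip[chrom], c2.chip[chrom])


class TestSimulateExpression:
    def _setup(self, **kwargs):
        cfg = SimConfig(seed=4, **kwargs)
        ann = generate_genome(cfg)
        truth = plant_blocks(ann, cfg)
        return cfg, ann, truth

    def test_no_repression_no_group_difference(self):
        cfg, ann, truth = self._setup(repression_strength=0.0)
        table = simulate_expression(ann, truth, cfg).table
        in_block = truth.gene_in_block(ann)
        a = np.log(table.loc[in_block, "control"])
        b = np.log(table.loc[~in_block, "control"])
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_planted_repression_magnitude(self):
        cfg, ann, truth = self._setup(n_genes=900, chrom_length=2_500_000,
                                      repression_strength=2.0,
                                      expression_noise_sd=0.5)
        table = simulate_expression(ann, truth, cfg).table
        in_block = truth.gene_in_block(ann)
        assert in_block.sum() >= 30 and (~in_block).sum() >= 200
        a = np.log(table.loc[in_block, "control"])
        b = np.log(table.loc[~in_block, "control"])
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs((b.mean() - a.mean()) - 2.0) < 3 * se

    def test_full_derepression_without_clusters(self):
        # no clustered genes: with derepressed_fraction = 1 and strong
        # coupling relative to noise, every block gene rises >= 1.5-fold
        cfg = SimConfig(seed=8, fraction_clustered=0.0, derepressed_fraction=1.0,
                        repression_strength=2.0, expression_noise_sd=0.02,
                        n_intergenic_blocks=2)
        ann = generate_genome(cfg)
        truth = plant_blocks(ann, cfg, over_clusters=False)
        table = simulate_expression(ann, truth, cfg).table
        in_block = truth.gene_in_block(ann)
        if in_block.sum():
            fc = table.loc[in_block, "kd"] / table.loc[in_block, "control"]
            assert (fc >= 1.5).all()

    def test_clustered_genes_stay_repressed(self, default_config):
        ann = generate_genome(default_config)
        truth = plant_blocks(ann, default_config)
        clusters = detect_clusters(ann)
        table = simulate_expression(ann, truth, default_config, clusters).table
        clustered = table.index.isin(sorted(clusters.gene_ids()))
        in_block = truth.gene_in_block(ann).to_numpy()
        fc = np.log(table["kd"] / table["control"])[clustered & in_block]
        # mean log fold change of clustered block genes is noise around 0
        assert abs(fc.mean()) < 3 * fc.std() / np.sqrt(len(fc)) + 0.1

    def test_determinism(self, default_config):
        ann = generate_genome(default_config)
        truth = plant_blocks(ann, default_config)
        a = simulate_expression(ann, truth, default_config).table
        b = simulate_expression(ann, truth, default_config).table
        pd.testing.assert_frame_equal(a, b)


class TestOraclePeakSet:
    def test_every_block_window_is_a_peak(self, three_gene_cluster):
        cfg = SimConfig(seed=0, n_intergenic_blocks=0)
        truth = plant_blocks(three_gene_cluster, cfg)
        peaks = oracle_peak_set(truth, three_gene_cluster.chrom_sizes)
        # block [7000, 28000) covers windows 70..279
        assert len(peaks) == 210
        idx = peaks.window_index("chr1")
        assert idx.min() == 70 and idx.max() == 279
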