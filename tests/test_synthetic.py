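import numpy as np
import pandas as pd
import pytest

from pombechip import synthetic
from pombechip.annotation_io import validate_catalog
from pombechip.synthetic import ConfigError, SynthConfig


def small_config(seed=1, **kw):
    cfg = SynthConfig(seed=seed, n_genes=600)
    cfg.chip.n_candidate_islands = 10
    cfg.chip.n_methylated_islands = 4
    cfg.chip.n_lost_islands = 3
    cfg.ripchip.n_targets = 20
    cfg.expression.n_de = 20
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


class TestMakeGenome:
    def test_default_catalog_is_valid_with_required_classes(self, default_study):
        _, catalog, _ = default_study
        assert validate_catalog(catalog) == []
        assert len(catalog.by_class("island")) >= 6
        assert len(catalog.by_class("subtelomere")) == 8  # 4 blocks + 4 distal
        assert len(catalog.by_class("centromere")) == 1
        assert len(catalog.by_class("transposon", "HOOD")) >= 2

    def test_islands_overlap_genes_but_not_reserved_blocks(self, default_study):
        _, catalog, _ = default_study
        genes = catalog.genes
        blocks = catalog.by_class("subtelomere", "centromere", "transposon", "HOOD")
        for isl in catalog.by_class("island"):
            assert any(isl.overlaps(g) for g in genes)
            assert not any(isl.overlaps(b) for b in blocks)

    def test_determinism(self):
        a = synthetic.make_genome(small_config())
        b = synthetic.make_genome(small_config())
        assert [
            (f.feature_id, f.chrom, f.start, f.end, f.strand, f.fclass) for f in a
        ] == [(f.feature_id, f.chrom, f.start, f.end, f.strand, f.fclass) for f in b]

    def test_no_genes_still_places_chromatin_blocks(self):
        cfg = small_config(n_genes=0)
        cfg.ripchip.n_targets = 0
        cfg.expression.n_de = 0
        catalog = synthetic.make_genome(cfg)
        assert len(catalog.genes) == 0
        assert len(catalog.by_class("island")) == 10
        assert validate_catalog(catalog) == []

    def test_infeasible_placement_rejected(self):
        cfg = small_config(n_genes=500_000)
        cfg.ripchip.n_targets = 1
        cfg.expression.n_de = 1
        with pytest.raises(ConfigError, match="too small"):
            synthetic.make_genome(cfg)

    def test_invalid_config_rejected(self):
        cfg = small_config()
        cfg.ripchip.n_targets = 10_000
        with pytest.raises(ConfigError, match="n_targets"):
            cfg.validate()


class TestTruth:
    def test_all_planted_ids_exist_in_catalog(self, default_study):
        _, catalog, truth = default_study
        ids = set(catalog.ids())
        assert truth.target_ids <= ids
        assert truth.de_ids <= ids
        for domain_set in truth.methylated_domains.values():
            assert domain_set <= ids

    def test_distal_subtelomeres_never_lost(self, default_study):
        _, _, truth = default_study
        lost = truth.lost_domains("ccr4")
        assert not any(d.endswith("_distal") for d in lost)
        assert len(lost) > 0


class TestRipchipGenerator:
    def test_target_mean_near_effect(self, default_study):
        cfg, catalog, truth = default_study
        m = synthetic.simulate_ripchip(cfg, truth, catalog)
        targets = m.values.loc[sorted(truth.target_ids)]
        n = targets.size
        se = cfg.ripchip.noise_sd / np.sqrt(n)
        assert abs(targets.to_numpy().mean() - cfg.ripchip.target_effect) < 3 * se

    def test_zero_noise_degenerate(self):
        cfg = small_config()
        cfg.ripchip.noise_sd = 0.0
        catalog = synthetic.make_genome(cfg)
        truth = synthetic.make_truth(cfg, catalog)
        m = synthetic.simulate_ripchip(cfg, truth, catalog)
        tgt = sorted(truth.target_ids)
        others = m.values.index.difference(tgt)
        assert (m.values.loc[tgt] == cfg.ripchip.target_effect).all().all()
        assert (m.values.loc[others] == 0.0).all().all()

    def test_seed_determinism(self, default_study):
        cfg, catalog, truth = default_study
        a = synthetic.simulate_ripchip(cfg, truth, catalog)
        b = synthetic.simulate_ripchip(cfg, truth, catalog)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestExpressionGenerator:
    def test_no_de_centred_at_zero(self):
        cfg = small_config()
        cfg.expression.n_de = 0
        catalog = synthetic.make_genome(cfg)
        truth = synthetic.make_truth(cfg, catalog)
        m, _ = synthetic.simulate_expression(cfg, truth, catalog)
        assert abs(m.values.to_numpy().mean()) < 0.05

    def test_signed_fold_changes_planted(self):
        cfg = small_config()
        cfg.expression.noise_sd = 0.0
        catalog = synthetic.make_genome(cfg)
        truth = synthetic.make_truth(cfg, catalog)
        m, _ = synthetic.simulate_expression(cfg, truth, catalog)
        for gid, fc in truth.de_log2fc.items():
            assert (m.values.loc[gid] == fc).all()
        assert {abs(v) for v in truth.de_log2fc.values()} == {cfg.expression.de_log2fc}

    def test_dye_bias_changes_raw_trend(self):
        cfg = small_config()
        cfg.expression.dye_bias_amplitude = 1.0
        catalog = synthetic.make_genome(cfg)
        truth = synthetic.make_truth(cfg, catalog)
        m, inten = synthetic.simulate_expression(cfg, truth, catalog)
        from pombechip.diffexpr import trend_amplitude

        assert (trend_amplitude(m, inten) > 0.5).all()


class TestChipGenerator:
    def test_density_ratio_matches_enrichment(self, default_study):
        cfg, catalog, truth = default_study
        reads = synthetic.simulate_chip_reads(cfg, truth, catalog, "wt")
        me2 = [r for r in reads if r.sample.antibody == "H3K9me2"][0]
        domains = [
            f for f in catalog.features if f.feature_id in truth.methylated_domains["wt"]
        ]
        dom_len = sum(f.length for f in domains)
        genome_len = sum(catalog.chrom_sizes.values())
        inside = sum(
            np.count_nonzero(
                (me2.starts[f.chrom] >= f.start) & (me2.starts[f.chrom] < f.end)
            )
            for f in domains
        )
        outside = me2.n_reads - inside
        density_ratio = (inside / dom_len) / (outside / (genome_len - dom_len))
        assert density_ratio == pytest.approx(cfg.chip.island_me2_enrichment, rel=0.1)

    def test_full_retention_statistically_identical_to_wt(self, default_study):
        cfg, catalog, truth = default_study
        cfg2 = SynthConfig(seed=cfg.seed)
        cfg2.chip.mutant_loss_fraction = 1.0
        wt = synthetic.simulate_chip_reads(cfg2, truth, catalog, "wt")
        mut = synthetic.simulate_chip_reads(cfg2, truth, catalog, "ccr4")
        lost = [
            f for f in catalog.features if f.feature_id in truth.lost_domains("ccr4")
        ]
        for f in lost[:3]:
            w = [r for r in wt if r.sample.antibody == "H3K9me2"][0]
            m = [r for r in mut if r.sample.antibody == "H3K9me2"][0]
            cw = np.count_nonzero((w.starts[f.chrom] >= f.start) & (w.starts[f.chrom] < f.end))
            cm = np.count_nonzero((m.starts[f.chrom] >= f.start) & (m.starts[f.chrom] < f.end))
            assert abs(cw - cm) < 5 * np.sqrt(max(cw, cm, 1))

    def test_seed_determinism_of_read_coordinates(self, default_study):
        cfg, catalog, truth = default_study
        a = synthetic.simulate_chip_reads(cfg, truth, catalog, "wt")
        b = synthetic.simulate_chip_reads(cfg, truth, catalog, "wt")
        for ra, rb in zip(a, b):
            assert str(ra.sample) == str(rb.sample)
            for chrom in ra.starts:
                assert np.array_equal(ra.starts[chrom], rb.starts[chrom])

    def test_substreams_independent_of_call_order(self, default_study):
        cfg, catalog, truth = default_study
        m1 = synthetic.simulate_ripchip(cfg, truth, catalog)
        _ = synthetic.simulate_qpcr(cfg)
        m2 = synthetic.simulate_ripchip(cfg, truth, catalog)
        pd.testing.assert_frame_equal(m1.values, m2.values)
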