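import numpy as np
import pandas as pd
import pytest

from pombechip import synthetic
from pombechip.annotation_io import FeatureCatalog, GenomicFeature
from pombechip.occupancy import (
    ReadSet,
    SampleKey,
    background_ratio,
    compare_conditions,
    count_reads,
    detect_enriched,
    h3_normalize,
    quantify,
    read_bed_reads,
    read_sam_reads,
    rpkm,
    write_bedgraph,
)


def readset(starts: dict, antibody="H3K9me2", condition="wt", rep=1, length=50):
    return ReadSet(
        sample=SampleKey(antibody, condition, rep),
        starts={c: np.asarray(v, dtype=np.int64) for c, v in starts.items()},
        read_length=length,
    )


@pytest.fixture
def flat_catalog():
    return FeatureCatalog(
        features=[
            GenomicFeature("f1", "chr1", 100, 200),
            GenomicFeature("f2", "chr1", 150, 300),  # overlaps f1
            GenomicFeature("f3", "chr2", 0, 1000),
        ],
        chrom_sizes={"chr1": 1000, "chr2": 1000},
    )


class TestCountReads:
    def test_start_point_rule_boundaries(self, flat_catalog):
        rs = readset({"chr1": [99, 100, 199, 200]})
        counts = count_reads(rs, flat_catalog)
        # 99 is 1 bp before the feature; 199 is the last position inside
        assert counts["f1"] == 2
        assert counts["f2"] == 2  # 199 and 200 fall in [150, 300)
        assert counts["f3"] == 0

    def test_overlapping_features_both_receive_read(self, flat_catalog):
        counts = count_reads(readset({"chr1": [175]}), flat_catalog)
        assert counts["f1"] == 1 and counts["f2"] == 1

    def test_unknown_chromosome_named(self, flat_catalog):
        with pytest.raises(ValueError, match="chrX"):
            count_reads(readset({"chrX": [5]}), flat_catalog)

    def test_uniform_reads_proportional_to_feature_span(self):
        cat = FeatureCatalog(
            features=[GenomicFeature("tenth", "chr1", 0, 10_000)],
            chrom_sizes={"chr1": 100_000},
        )
        rng = np.random.default_rng(0)
        rs = readset({"chr1": rng.integers(0, 100_000, size=10_000)})
        count = count_reads(rs, cat)["tenth"]
        assert abs(count - 1000) < 4 * np.sqrt(1000)  # Poisson tolerance

    def test_midpoint_assignment_option(self, flat_catalog):
        rs = readset({"chr1": [80]}, length=50)  # midpoint 105 inside f1
        assert count_reads(rs, flat_catalog, assign_by="midpoint")["f1"] == 1
        assert count_reads(rs, flat_catalog, assign_by="start")["f1"] == 0


class TestRpkm:
    def test_direct_formula(self, flat_catalog):
        cat = FeatureCatalog(
            features=[GenomicFeature("f", "chr1", 0, 1000)], chrom_sizes={"chr1": 2000}
        )
        counts = pd.Series({"f": 10}, name="s")
        assert rpkm(counts, cat, 1_000_000)["f"] == pytest.approx(10.0)

    def test_zero_reads(self, flat_catalog):
        counts = pd.Series({"f1": 0, "f2": 0, "f3": 0}, name="s")
        assert (rpkm(counts, flat_catalog, 500_000) == 0).all()

    def test_duplication_invariance(self, flat_catalog):
        counts = pd.Series({"f1": 7, "f2": 3, "f3": 11}, name="s")
        a = rpkm(counts, flat_catalog, 10_000)
        b = rpkm(counts * 2, flat_catalog, 20_000)
        pd.testing.assert_series_equal(a, b)

    def test_invalid_library_size(self, flat_catalog):
        with pytest.raises(ValueError):
            rpkm(pd.Series({"f1": 1}, name="s"), flat_catalog, 0)


class TestH3Normalize:
    def test_ratio_zero_and_undefined(self):
        me2 = pd.Series({"a": 10.0, "b": 0.0, "c": 4.0})
        h3 = pd.Series({"a": 5.0, "b": 5.0, "c": 0.0})
        r = h3_normalize(me2, h3)
        assert r["a"] == 2.0 and r["b"] == 0.0
        assert np.isnan(r["c"])  # undefined, not zero


@pytest.fixture(scope="module")
def study():
    cfg = synthetic.SynthConfig(seed=21)
    catalog = synthetic.make_genome(cfg)
    truth = synthetic.make_truth(cfg, catalog)
    reads = {
        cond: synthetic.simulate_chip_reads(cfg, truth, catalog, cond)
        for cond in ("wt", "ccr4")
    }
    table = quantify(reads["wt"] + reads["ccr4"], catalog)
    return cfg, catalog, truth, table


class TestSyntheticOccupancy:
    def test_me2_density_ratio_matches_planted_enrichment(self, study):
        cfg, catalog, truth, table = study
        het = [f.feature_id for f in catalog.heterochromatin]
        bg = background_ratio(table.ratios["wt"], catalog)
        norm = (table.ratios["wt"] / bg).mean(axis=1)
        planted = sorted(truth.methylated_domains["wt"])
        assert norm[planted].mean() == pytest.approx(
            cfg.chip.island_me2_enrichment, rel=0.1
        )

    def test_detect_enriched_recovers_planted_domains(self, study):
        _, catalog, truth, table = study
        flagged = set(detect_enriched(table.ratios["wt"], catalog))
        assert flagged == truth.methylated_domains["wt"]

    def test_flagged_set_monotone_in_enrichment_factor(self, study):
        _, catalog, _, table = study
        sizes = [
            len(detect_enriched(table.ratios["wt"], catalog, enrichment_factor=f))
            for f in (1.5, 2.0, 4.0, 10.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_compare_conditions_recovers_lost_domains(self, study):
        _, catalog, truth, table = study
        het = [f.feature_id for f in catalog.heterochromatin]
        cmp = compare_conditions(
            table.ratios["wt"].loc[het],
            table.ratios["ccr4"].loc[het],
            wt_background=background_ratio(table.ratios["wt"], catalog),
            mutant_background=background_ratio(table.ratios["ccr4"], catalog),
        )
        reduced = set(cmp.index[cmp["call"] == "reduced"])
        assert reduced == truth.lost_domains("ccr4")
        distal = {i for i in het if i.endswith("_distal")}
        assert not reduced & distal

    def test_h3_occupancy_unchanged_where_me2_lost(self, study):
        _, catalog, truth, table = study
        het = [f.feature_id for f in catalog.heterochromatin]
        cmp = compare_conditions(
            table.ratios["wt"].loc[het],
            table.ratios["ccr4"].loc[het],
            wt_h3=table.h3_rpkm("wt").loc[het],
            mutant_h3=table.h3_rpkm("ccr4").loc[het],
        )
        lost = sorted(truth.lost_domains("ccr4"))
        assert cmp.loc[lost, "h3_fold"].between(0.8, 1.25).all()


def test_full_retention_mutant_calls_no_reductions():
    """mutant_loss_fraction = 1 is the null case: no feature may be called."""
    cfg = synthetic.SynthConfig(seed=8)
    cfg.chip.mutant_loss_fraction = 1.0
    catalog = synthetic.make_genome(cfg)
    truth = synthetic.make_truth(cfg, catalog)
    reads = [
        r
        for cond in ("wt", "ccr4")
        for r in synthetic.simulate_chip_reads(cfg, truth, catalog, cond)
    ]
    table = quantify(reads, catalog)
    het = [f.feature_id for f in catalog.heterochromatin]
    cmp = compare_conditions(
        table.ratios["wt"].loc[het],
        table.ratios["ccr4"].loc[het],
        wt_background=background_ratio(table.ratios["wt"], catalog),
        mutant_background=background_ratio(table.ratios["ccr4"], catalog),
    )
    assert (cmp["call"] == "unchanged").all()


class TestCompareConditionsEdgeCases:
    def test_identical_conditions_all_unchanged(self):
        df = pd.DataFrame({"rep1": [4.0, 1.0], "rep2": [4.2, 1.1]}, index=["a", "b"])
        cmp = compare_conditions(df, df.copy())
        assert (cmp["call"] == "unchanged").all()
        assert cmp["fold"].tolist() == pytest.approx([1.0, 1.0])

    def test_undefined_ratio_reported_not_dropped(self):
        wt = pd.DataFrame({"r1": [4.0, np.nan]}, index=["a", "b"])
        mu = pd.DataFrame({"r1": [1.0, 2.0]}, index=["a", "b"])
        cmp = compare_conditions(wt, mu)
        assert cmp.loc["a", "call"] == "reduced"
        assert cmp.loc["b", "call"] == "not_evaluable"
        assert set(cmp.index) == {"a", "b"}

    def test_increase_called_symmetrically(self):
        wt = pd.DataFrame({"r1": [1.0], "r2": [1.1]}, index=["a"])
        mu = pd.DataFrame({"r1": [4.0], "r2": [4.4]}, index=["a"])
        assert compare_conditions(wt, mu)["call"].iloc[0] == "increased"


class TestReadIO:
    def test_bed_round_trip(self, tmp_path):
        rs = readset({"chr1": [5, 100], "chr2": [7]})
        p = rs.to_bed(tmp_path / "r.bed")
        back = read_bed_reads(p, rs.sample)
        assert {c: v.tolist() for c, v in back.starts.items()} == {
            "chr1": [5, 100],
            "chr2": [7],
        }

    def test_sam_primary_alignments_only(self, tmp_path, flat_catalog):
        sam = tmp_path / "r.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:chr1\tLN:1000\n"
            "r1\t0\tchr1\t101\t60\t50M\t*\t0\t0\t*\t*\n"  # 1-based 101 -> 0-based 100
            "r2\t256\tchr1\t151\t60\t50M\t*\t0\t0\t*\t*\n"  # secondary: skipped
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"  # unmapped: skipped
        )
        rs = read_sam_reads(sam, SampleKey("H3", "wt", 1))
        assert rs.starts["chr1"].tolist() == [100]
        assert count_reads(rs, flat_catalog)["f1"] == 1

    def test_bedgraph_track(self, tmp_path):
        me2 = readset({"chr1": [0, 10, 600]}, antibody="H3K9me2")
        h3 = readset({"chr1": [5, 550]}, antibody="H3")
        p = write_bedgraph(me2, h3, {"chr1": 1000}, tmp_path / "t.bedgraph")
        lines = p.read_text().splitlines()
        assert lines[0].startswith("track type=bedGraph")
        assert len(lines) == 3  # two bins have H3 coverage


def test_raw_count_conservation(flat_catalog):
    rs = readset({"chr1": [10, 110, 160, 500], "chr2": [5]})
    counts = count_reads(rs, flat_catalog)
    non_overlapping = counts[["f1", "f3"]].sum()
    assert non_overlapping <= rs.n_reads
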