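import numpy as np
import pandas as pd
import pytest

from pombechip import synthetic
from pombechip.diffexpr import (
    called_sets,
    default_s0,
    fold_change,
    loess_normalize,
    median_centre,
    percentile_s0,
    sam_fdr,
    sam_statistic,
    trend_amplitude,
    write_de_results,
)
from pombechip.matrix import EnrichmentMatrix


def em(data: dict, index=None) -> EnrichmentMatrix:
    return EnrichmentMatrix(values=pd.DataFrame(data, index=index), channel="expression")


class TestMedianCentre:
    def test_odd_column(self):
        out = median_centre(em({"r1": [1.0, 2.0, 4.0]}))
        assert out.values["r1"].tolist() == [-1.0, 0.0, 2.0]

    def test_even_column_uses_midpoint_median(self):
        out = median_centre(em({"r1": [-5.0, 0.0, 5.0, 100.0]}))
        assert out.values["r1"].tolist() == [-7.5, -2.5, 2.5, 97.5]

    def test_idempotent(self):
        once = median_centre(em({"r1": [3.0, -1.0, 0.0, 8.0]}))
        twice = median_centre(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestLoess:
    @staticmethod
    def _biased_study(amplitude):
        cfg = synthetic.SynthConfig(seed=4, n_genes=1000)
        cfg.chip.n_candidate_islands = 10
        cfg.expression.dye_bias_amplitude = amplitude
        cfg.expression.n_de = 0
        catalog = synthetic.make_genome(cfg)
        truth = synthetic.make_truth(cfg, catalog)
        return synthetic.simulate_expression(cfg, truth, catalog)

    def test_trendless_input_nearly_unchanged(self):
        matrix, inten = self._biased_study(0.0)
        out = loess_normalize(matrix, inten)
        resid = trend_amplitude(out, inten)
        assert (resid < 0.1).all()

    def test_planted_dye_bias_removed(self):
        matrix, inten = self._biased_study(1.0)
        before = trend_amplitude(matrix, inten)
        assert (before > 0.5).all()  # the planted trend is visible
        out = loess_normalize(matrix, inten)
        after = trend_amplitude(out, inten)
        assert (after < 0.1).all()

    def test_constant_offset_is_a_trend(self):
        matrix, inten = self._biased_study(0.0)
        shifted = matrix.with_values(matrix.values + 2.0)
        out = loess_normalize(shifted, inten)
        assert abs(out.values.mean().mean()) < 0.05

    def test_too_few_points_rejected(self):
        m = em({"r1": [0.1] * 5})
        inten = pd.DataFrame({"r1": np.arange(5.0)})
        with pytest.raises(ValueError, match="r1"):
            loess_normalize(m, inten)


class TestSamStatistic:
    def test_all_zero_gene_is_zero(self):
        d = sam_statistic(em({"a": [0.0], "b": [0.0], "c": [0.0]}), s0=0.2)
        assert d.iloc[0] == 0.0

    def test_zero_variance_limit(self):
        d = sam_statistic(em({"a": [1.0], "b": [1.0], "c": [1.0]}), s0=0.1)
        assert d.iloc[0] == pytest.approx(1 / 0.1)

    def test_worked_example(self):
        # replicates [2, 4]: mean 3, se 1, d = 3 / 1.1
        d = sam_statistic(em({"a": [2.0], "b": [4.0]}), s0=0.1)
        assert d.iloc[0] == pytest.approx(3 / 1.1)
        assert d.iloc[0] == pytest.approx(2.727, abs=1e-3)

    def test_single_replicate_gene_missing(self):
        d = sam_statistic(em({"a": [2.0, 1.0], "b": [np.nan, 2.0]}), s0=0.1)
        assert np.isnan(d.iloc[0]) and np.isfinite(d.iloc[1])

    def test_replicate_order_invariance(self):
        a = em({"a": [0.5, 1.0], "b": [1.5, -1.0], "c": [1.0, 0.3]})
        b = em({"c": [1.0, 0.3], "a": [0.5, 1.0], "b": [1.5, -1.0]})
        assert sam_statistic(a, s0=0.1).tolist() == pytest.approx(
            sam_statistic(b, s0=0.1).tolist()
        )

    def test_s0_defaults(self):
        m = em({c: np.random.default_rng(0).normal(size=50) for c in "abc"})
        assert percentile_s0(m, 5.0) <= percentile_s0(m, 95.0)
        assert default_s0(m) >= 0


class TestSamFdr:
    def test_requires_seed_and_enough_permutations(self, small_matrix):
        m = em(dict(small_matrix.values))
        with pytest.raises(ValueError, match="seed"):
            sam_fdr(m, n_permutations=60, seed=None)
        with pytest.raises(ValueError, match="permutations"):
            sam_fdr(m, n_permutations=10, seed=1)

    def test_bit_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(7)
        m = em({c: rng.normal(size=300) for c in "abc"})
        r1 = sam_fdr(m, n_permutations=60, seed=9)
        r2 = sam_fdr(m, n_permutations=60, seed=9)
        assert [(r.gene_id, r.d_stat, r.q_value, r.called) for r in r1] == [
            (r.gene_id, r.d_stat, r.q_value, r.called) for r in r2
        ]

    def test_single_all_zero_gene_not_called(self):
        m = em({"a": [0.0], "b": [0.0], "c": [0.0]})
        (res,) = sam_fdr(m, n_permutations=60, seed=1)
        assert res.q_value == 1.0 and not res.called

    def test_planted_signal_called_with_direction(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.3, size=(400, 3))
        vals[:10] += 2.0
        vals[10:20] -= 2.0
        m = em({f"r{i}": vals[:, i] for i in range(3)}, index=[f"g{i}" for i in range(400)])
        res = sam_fdr(m, n_permutations=100, seed=2, fdr_threshold=0.01)
        up, down = called_sets(res)
        assert {f"g{i}" for i in range(10)} <= up
        assert {f"g{i}" for i in range(10, 20)} <= down
        # q-values live in [0, 1] and called implies q below threshold
        assert all(0 <= r.q_value <= 1 for r in res)
        assert all(r.q_value < 0.01 for r in res if r.called)


class TestFoldChange:
    @pytest.mark.parametrize("mean_log2, expected", [(1.0, 2.0), (0.0, 1.0)])
    def test_simple(self, mean_log2, expected):
        m = em({"a": [mean_log2]}, index=["g"])
        assert fold_change(m, "g") == pytest.approx(expected)

    def test_caf1_style_fold(self):
        m = em({"a": [0.7], "b": [1.0]}, index=["mei4"])
        assert fold_change(m, "mei4") == pytest.approx(2 ** 0.85)
        assert fold_change(m, "mei4") == pytest.approx(1.80, abs=0.01)

    def test_missing_gene_and_all_nan(self):
        m = em({"a": [np.nan]}, index=["g"])
        with pytest.raises(KeyError):
            fold_change(m, "other")
        with pytest.raises(ValueError, match="missing"):
            fold_change(m, "g")


def test_de_results_table_round_trip(tmp_path):
    m = em({"a": [1.0, 0.0], "b": [1.2, 0.1], "c": [0.9, -0.1]}, index=["up", "null"])
    res = sam_fdr(m, n_permutations=60, seed=1)
    path = write_de_results(res, tmp_path / "de.tsv")
    table = pd.read_csv(path, sep="\t")
    assert list(table.columns) == [
        "gene_id", "mean_log2fc", "fold_change", "d_stat", "q_value", "direction",
    ]
    assert len(table) == 2
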