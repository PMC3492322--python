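"""Over-expression screen, marker calls, and expression-content summaries."""

import numpy as np
import pandas as pd
import pytest

from ctcseq.screen import (
    MarkerPanel,
    ScreenConfig,
    marker_call,
    origin_call,
    overexpression_screen,
    pairwise_count_correlation,
    transcript_count_summary,
    variable_gene_count,
)


def naive_screen(ctc_fpkm, ctc_counts, normal_fpkm, config):
    """Exhaustive reference implementation with plain python sorting."""
    rows = {}
    for gene in ctc_fpkm.index:
        vals = sorted(ctc_fpkm.loc[gene].tolist(), reverse=True)
        rank_th = vals[config.rank - 1]
        denom = max(float(normal_fpkm[gene]), config.denominator_floor)
        ratio = rank_th / denom
        reads = max(np.floor(c + 0.5) for c in ctc_counts.loc[gene].tolist())
        rows[gene] = (ratio, reads, ratio >= config.ratio_threshold and reads >= config.min_reads)
    return rows


def make_matrices(genes, ctc_fpkm_rows, counts_value=50.0):
    fpkm = pd.DataFrame(ctc_fpkm_rows, index=genes)
    fpkm.columns = [f"c{i}" for i in range(fpkm.shape[1])]
    counts = pd.DataFrame(counts_value, index=fpkm.index, columns=fpkm.columns)
    return fpkm, counts


class TestOverexpressionScreen:
    def test_second_highest_ratio_and_selection(self):
        fpkm, counts = make_matrices(["g"], [[400.0, 250.0, 0.0, 0.0, 0.0]])
        res = overexpression_screen(fpkm, counts, pd.Series({"g": 2.0}))
        row = res.iloc[0]
        assert row.second_highest_fpkm == pytest.approx(250.0)
        assert row.ratio == pytest.approx(125.0)
        assert bool(row.selected)

    def test_ratio_just_below_threshold_not_selected(self):
        fpkm, counts = make_matrices(["g"], [[500.0, 99.9, 0.0]])
        res = overexpression_screen(fpkm, counts, pd.Series({"g": 1.0}))
        assert res.iloc[0].ratio == pytest.approx(99.9)
        assert not bool(res.iloc[0].selected)

    def test_ratio_exactly_at_threshold_selected(self):
        fpkm, counts = make_matrices(["g"], [[500.0, 100.0, 0.0]])
        res = overexpression_screen(fpkm, counts, pd.Series({"g": 1.0}))
        assert bool(res.iloc[0].selected)

    def test_read_support_rule(self):
        fpkm, counts = make_matrices(["g"], [[1000.0, 500.0, 0.0]], counts_value=9.0)
        res = overexpression_screen(fpkm, counts, pd.Series({"g": 1.0}))
        assert res.iloc[0].ratio == pytest.approx(500.0)
        assert not bool(res.iloc[0].selected)
        # 9.5 rounds half-up to 10 and flips the verdict
        counts[:] = 9.5
        res = overexpression_screen(fpkm, counts, pd.Series({"g": 1.0}))
        assert bool(res.iloc[0].selected)

    def test_zero_normal_uses_denominator_floor(self):
        fpkm, counts = make_matrices(["g"], [[5.0, 2.0, 0.0]])
        res = overexpression_screen(fpkm, counts, pd.Series({"g": 0.0}))
        assert res.iloc[0].normal_fpkm == pytest.approx(0.01)
        assert res.iloc[0].ratio == pytest.approx(200.0)

    def test_fewer_ctcs_than_rank_rejected(self):
        fpkm, counts = make_matrices(["g"], [[5.0]])
        with pytest.raises(ValueError, match="at least 2 CTC samples"):
            overexpression_screen(fpkm, counts, pd.Series({"g": 1.0}))

    def test_matches_naive_oracle_on_random_matrices(self, rng):
        config = ScreenConfig()
        for _ in range(40):
            n_genes = int(rng.integers(1, 51))
            n_ctc = int(rng.integers(2, 7))
            genes = [f"g{i}" for i in range(n_genes)]
            fpkm = pd.DataFrame(
                rng.uniform(0, 300, size=(n_genes, n_ctc)),
                index=genes, columns=[f"c{j}" for j in range(n_ctc)],
            )
            counts = pd.DataFrame(
                rng.uniform(0, 40, size=(n_genes, n_ctc)),
                index=fpkm.index, columns=fpkm.columns,
            )
            normal = pd.Series(rng.uniform(0, 3, size=n_genes), index=genes)
            res = overexpression_screen(fpkm, counts, normal, config).set_index("gene")
            expected = naive_screen(fpkm, counts, normal, config)
            for gene, (ratio, reads, selected) in expected.items():
                assert res.loc[gene, "ratio"] == pytest.approx(ratio)
                assert res.loc[gene, "max_ctc_reads"] == reads
                assert bool(res.loc[gene, "selected"]) == selected

    def test_tightening_thresholds_never_adds_genes(self, rng):
        genes = [f"g{i}" for i in range(30)]
        fpkm = pd.DataFrame(rng.uniform(0, 500, (30, 5)), index=genes)
        counts = pd.DataFrame(rng.uniform(0, 30, (30, 5)), index=genes,
                              columns=fpkm.columns)
        normal = pd.Series(rng.uniform(0, 3, 30), index=genes)
        loose = overexpression_screen(fpkm, counts, normal, ScreenConfig())
        for tighter in (ScreenConfig(ratio_threshold=200), ScreenConfig(min_reads=20)):
            tight = overexpression_screen(fpkm, counts, normal, tighter)
            assert set(tight[tight.selected].gene) <= set(loose[loose.selected].gene)

    def test_recovers_planted_folds_on_noiseless_cohort(self, noiseless_cohort):
        matrix, truth = noiseless_cohort
        ctc = matrix.samples_in_group("ctc")
        normal = matrix.fpkm[matrix.samples_in_group("normal_prostate")].mean(axis=1)
        res = overexpression_screen(matrix.fpkm[ctc], matrix.counts[ctc], normal)
        selected = set(res[res.selected].gene)
        expected = {g for g, d in truth.true_overexpressed.items() if d["fold"] >= 100}
        assert selected == expected


class TestVariableGeneCount:
    def test_bimodal_gene_counted(self):
        fpkm = pd.DataFrame([[12.0, 0.05], [5.0, 5.0]], index=["g1", "g2"])
        assert variable_gene_count(fpkm) == 1

    def test_in_range_gene_not_counted(self):
        fpkm = pd.DataFrame([[0.1, 10.0]], index=["g"])
        assert variable_gene_count(fpkm) == 0  # boundaries are strict

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            variable_gene_count(pd.DataFrame([[1.0]], index=["g"]))

    def test_planted_bimodal_truth_recovered(self, rng):
        n_genes, n_bimodal = 500, 37
        background = rng.uniform(0.2, 9.0, size=(n_genes, 4))
        fpkm = pd.DataFrame(background, index=[f"g{i}" for i in range(n_genes)])
        planted = rng.choice(n_genes, size=n_bimodal, replace=False)
        fpkm.iloc[planted, 0] = rng.uniform(11, 100, n_bimodal)
        fpkm.iloc[planted, 1] = rng.uniform(0, 0.09, n_bimodal)
        assert variable_gene_count(fpkm) == n_bimodal


class TestMarkerAndOriginCalls:
    def test_marker_tiers(self):
        assert marker_call(7.0) == (True, "strong")
        assert marker_call(3.0) == (True, "weak")
        assert marker_call(0.0) == (False, "negative")
        assert marker_call(1.0) == (False, "negative")  # strict >

    @pytest.mark.parametrize(
        "fpkm, expected",
        [
            ({"AR": 3, "KLK3": 0, "TMPRSS2": 0, "CD45": 0}, "prostate-like"),
            ({"AR": 0, "KLK3": 0, "TMPRSS2": 0, "CD45": 20}, "leukocyte-flagged"),
            ({"AR": 9, "KLK3": 9, "TMPRSS2": 9, "CD45": 20}, "leukocyte-flagged"),
            ({"AR": 0, "KLK3": 0, "TMPRSS2": 0, "CD45": 0}, "indeterminate"),
        ],
    )
    def test_origin_calls(self, fpkm, expected):
        assert origin_call(pd.Series(fpkm)) == expected

    def test_missing_marker_treated_as_zero(self):
        assert origin_call(pd.Series({"AR": 3.0})) == "prostate-like"

    def test_origin_calls_on_simulated_cohort(self, noisy_cohort):
        matrix, _ = noisy_cohort
        for sample in matrix.samples_in_group("ctc"):
            assert origin_call(matrix.fpkm[sample]) == "prostate-like"
        (wbc,) = matrix.samples_in_group("wbc")
        assert origin_call(matrix.fpkm[wbc]) == "leukocyte-flagged"


class TestTranscriptCountSummary:
    def test_threshold_is_non_strict(self):
        fpkm = pd.DataFrame({"s": [10.0, 9.99, 11.0]}, index=["a", "b", "c"])
        per_sample, summary = transcript_count_summary(fpkm)
        assert per_sample["s"] == 2
        assert summary["mean"] == 2.0

    def test_empty_matrix(self):
        per_sample, _ = transcript_count_summary(pd.DataFrame({"s": []}))
        assert per_sample["s"] == 0

    def test_summary_statistics(self):
        fpkm = pd.DataFrame(
            [[20.0, 20.0, 20.0], [20.0, 20.0, 0.0], [20.0, 0.0, 0.0]],
            columns=["s1", "s2", "s3"],
        )
        per_sample, summary = transcript_count_summary(fpkm)
        assert per_sample.tolist() == [3, 2, 1]
        assert summary == {"mean": 2.0, "sd": 1.0, "min": 1.0, "max": 3.0}


class TestPairwiseCountCorrelation:
    def test_duplicated_sample_has_unit_correlation(self, rng):
        counts = pd.DataFrame({"a": rng.poisson(20, 100)})
        counts["b"] = counts["a"]
        corr = pairwise_count_correlation(counts)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, rng):
        counts = pd.DataFrame(rng.poisson(10, size=(200, 4)), columns=list("abcd"))
        corr = pairwise_count_correlation(counts)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_independent_samples_near_zero(self, rng):
        counts = pd.DataFrame(rng.poisson(10, size=(5000, 2)), columns=["a", "b"])
        corr = pairwise_count_correlation(counts)
        assert abs(corr.loc["a", "b"]) < 0.05

    def test_zero_variance_sample_rejected(self):
        counts = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            pairwise_count_correlation(counts)


def test_screen_config_validation():
    with pytest.raises(ValueError):
        ScreenConfig(rank=0)
    with pytest.raises(ValueError):
        ScreenConfig(ratio_threshold=0)
    with pytest.raises(ValueError):
        MarkerPanel(positive_markers=("CD45",), negative_marker="CD45")
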