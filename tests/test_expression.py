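"""Expression processing: normalization, merging, PCA, DGE, BH, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pscpipe.expression import (
    DGEResult,
    ExpressionStudy,
    bh_adjust,
    fit_dge,
    group_mean_correlation,
    marker_anova,
    merge_technical_replicates,
    overlap_summary,
    pca_summary,
    quantile_normalize,
    select_degs,
)
from pscpipe.simulate import SimConfig, gen_expression_study


class TestQuantileNormalize:
    def test_hand_computed_rank_means(self, tiny_matrix):
        out = quantile_normalize(tiny_matrix)
        assert out["s1"].tolist() == [1.5, 3.5]
        assert out["s2"].tolist() == [1.5, 3.5]

    def test_identical_columns_are_fixed_point(self):
        m = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_idempotence(self, rng):
        m = pd.DataFrame(rng.normal(size=(40, 6)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_sorted_columns_identical_after_normalization(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 5)) * [1, 2, 3, 4, 5])
        out = quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            assert np.array_equal(np.sort(out[:, j]), ref)

    def test_ties_get_mean_of_tied_rank_targets(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        # rank targets: [1.5, 2.5, 5.5]; the tie in column a spans ranks 1-2
        assert out["a"].tolist() == [2.0, 2.0, 5.5]

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, np.nan]}))


class TestMergeTechnicalReplicates:
    def test_mean_of_two_replicates(self):
        matrix = pd.DataFrame({"s_r0": [2.0], "s_r1": [4.0]}, index=["g"])
        samples = pd.DataFrame(
            {"group": ["UD", "UD"], "tech_rep_group": ["s", "s"]},
            index=["s_r0", "s_r1"],
        )
        merged = merge_technical_replicates(ExpressionStudy(matrix, samples))
        assert merged.matrix.loc["g", "s"] == 3.0
        assert merged.n_samples == 1

    def test_singleton_group_unchanged(self):
        matrix = pd.DataFrame({"x_r0": [1.0, 2.0]}, index=["g1", "g2"])
        samples = pd.DataFrame({"group": ["FD"], "tech_rep_group": ["x"]},
                               index=["x_r0"])
        merged = merge_technical_replicates(ExpressionStudy(matrix, samples))
        assert merged.matrix["x"].tolist() == [1.0, 2.0]

    def test_column_count_matches_biological_samples(self):
        cfg = SimConfig(n_genes=20, n_samples_per_group=3, n_de_genes=2,
                        n_tech_reps=3, seed=2)
        matrix, samples, _ = gen_expression_study(cfg)
        merged = merge_technical_replicates(ExpressionStudy(matrix, samples))
        assert merged.n_samples == 2 * 3

    def test_conflicting_metadata_rejected(self):
        matrix = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g"])
        samples = pd.DataFrame(
            {"group": ["UD", "FD"], "tech_rep_group": ["s", "s"]},
            index=["a", "b"],
        )
        with pytest.raises(ValueError, match="conflicting"):
            merge_technical_replicates(ExpressionStudy(matrix, samples))


class TestPCASummary:
    def test_rank_one_data_gives_full_first_component(self, rng):
        direction = rng.normal(size=10)
        weights = rng.normal(size=6)
        m = pd.DataFrame(np.outer(direction, weights))
        res = pca_summary(m, k=2)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_two_orthogonal_equal_variance_directions(self):
        # two gene-space directions with identical sample variance
        m = pd.DataFrame([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        res = pca_summary(m, k=2)
        assert np.allclose(res.variance_fractions, [0.5, 0.5])

    def test_variance_fractions_non_increasing_and_bounded(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 8)))
        res = pca_summary(m, k=5)
        vf = res.variance_fractions
        assert np.all(np.diff(vf) <= 1e-12)
        assert vf.sum() <= 1.0 + 1e-9

    def test_planted_group_shift_separates_on_pc1(self):
        from sklearn.metrics import silhouette_score

        cfg = SimConfig(n_genes=200, n_samples_per_group=6, n_de_genes=100,
                        de_log2fc=4.0, noise_sd=0.5, seed=5)
        matrix, samples, _ = gen_expression_study(cfg)
        res = pca_summary(matrix, k=2)
        labels = samples.loc[res.scores.index, "group"].to_numpy()
        s = silhouette_score(res.scores[["PC1"]].to_numpy(), labels)
        assert s > 0

    def test_k_larger_than_rank_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            pca_summary(tiny_matrix, k=5)


class TestGroupMeanCorrelation:
    def test_identical_columns_correlate_perfectly(self, rng):
        col = rng.normal(size=20)
        m = pd.DataFrame({"a": col, "b": col, "c": col})
        res = group_mean_correlation(m, {"a": "g", "b": "g", "c": "g"})
        assert res["g"] == pytest.approx(1.0)

    def test_antiproportional_columns(self, rng):
        col = rng.normal(size=20)
        m = pd.DataFrame({"a": col, "b": -col})
        res = group_mean_correlation(m, {"a": "g", "b": "g"})
        assert res["g"] == pytest.approx(-1.0)

    def test_higher_noise_lowers_correlation(self):
        means = []
        for sd in (0.3, 2.0):
            vals = []
            for seed in range(5):
                cfg = SimConfig(n_genes=150, n_samples_per_group=5,
                                n_de_genes=0, noise_sd=sd, seed=seed)
                matrix, samples, _ = gen_expression_study(cfg)
                res = group_mean_correlation(matrix, samples["group"])
                vals.append(res.mean())
            means.append(np.mean(vals))
        assert means[0] > means[1]

    def test_constant_column_rejected(self):
        m = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            group_mean_correlation(m, {"a": "g", "b": "g"})


class TestFitDGE:
    def test_noiseless_recovery_exact(self, noiseless_study):
        study, truth, cfg = noiseless_study
        res = fit_dge(study, ("FD", "UD"))
        got = res.table.loc[truth["gene"], "log2fc"].to_numpy()
        assert np.allclose(got, truth["log2fc"].to_numpy(), atol=1e-10)
        others = res.table.index.difference(truth["gene"])
        assert np.allclose(res.table.loc[others, "log2fc"], 0.0, atol=1e-10)
        # residuals are zero up to float rounding, so p collapses to ~0
        assert (res.table.loc[truth["gene"], "p"] < 1e-50).all()

    def test_balanced_covariate_leaves_lfc_unchanged(self):
        cfg = SimConfig(n_genes=40, n_samples_per_group=6, n_de_genes=4,
                        noise_sd=0.8, seed=3)
        matrix, samples, _ = gen_expression_study(cfg)
        # perfectly balanced binary covariate, orthogonal to group
        samples = samples.copy()
        samples["balanced"] = (["x", "y"] * (len(samples) // 2))
        study = ExpressionStudy(matrix, samples)
        plain = fit_dge(study, ("FD", "UD"))
        adj = fit_dge(study, ("FD", "UD"), covariates=["balanced"])
        assert np.allclose(plain.table["log2fc"], adj.table["log2fc"], atol=1e-10)

    def test_adjusted_p_at_least_raw_p(self, noiseless_study):
        study, _, _ = noiseless_study
        res = fit_dge(study, ("FD", "UD"))
        assert (res.table["adj_p"] >= res.table["p"] - 1e-15).all()

    def test_confounded_design_names_columns(self):
        cfg = SimConfig(n_genes=10, n_samples_per_group=4, n_de_genes=2,
                        noise_sd=0.5, seed=1)
        matrix, samples, _ = gen_expression_study(cfg)
        samples = samples.copy()
        samples["confounded"] = samples["group"]  # perfectly collinear
        with pytest.raises(ValueError, match="confounded"):
            fit_dge(ExpressionStudy(matrix, samples), ("FD", "UD"),
                    covariates=["confounded"])


class TestBHAdjust:
    @pytest.mark.parametrize("pvals,expected", [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.01, 0.5], [0.02, 0.5]),
    ])
    def test_hand_cases(self, pvals, expected):
        assert np.allclose(bh_adjust(pvals), expected)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_permutation_equivariance(self, pvals, rnd):
        p = np.array(pvals)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        direct = bh_adjust(p)[perm]
        permuted = bh_adjust(p[perm])
        assert np.allclose(direct, permuted)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSelectDEGs:
    def _result(self, lfc, adj_p):
        table = pd.DataFrame({
            "log2fc": lfc, "p": adj_p, "adj_p": adj_p,
            "direction": ["up" if x >= 0 else "down" for x in lfc],
        }, index=[f"g{i}" for i in range(len(lfc))])
        return DGEResult(table=table, comparison="FD_vs_UD")

    def test_boundary_lfc_excluded_strictly(self):
        res = self._result([1.0, 1.0001], [0.01, 0.01])
        sel = select_degs(res)
        assert list(sel.index) == ["g1"]

    def test_direction_partition(self):
        res = self._result([2.0, -2.0], [0.04, 0.04])
        sel = select_degs(res)
        assert sel.loc["g0", "direction"] == "up"
        assert sel.loc["g1", "direction"] == "down"

    def test_noiseless_selection_equals_truth(self, noiseless_study):
        study, truth, _ = noiseless_study
        sel = select_degs(fit_dge(study, ("FD", "UD")))
        assert set(sel.index) == set(truth["gene"])


class TestOverlapSummary:
    def test_reported_study_arithmetic(self):
        a = [f"a{i}" for i in range(313)]
        b = a[:227] + [f"b{i}" for i in range(345 - 227)]
        s = overlap_summary(a, b)
        assert (s.n_a, s.n_b, s.n_overlap) == (313, 345, 227)
        assert s.percent_of_a == 72.5

    def test_equal_sets_and_disjoint_sets(self):
        assert overlap_summary(["x", "y"], ["x", "y"]).percent_of_a == 100.0
        assert overlap_summary(["x"], ["y"]).percent_of_a == 0.0

    def test_empty_a_rejected(self):
        with pytest.raises(ValueError):
            overlap_summary([], ["x"])


class TestMarkerAnova:
    def test_shifted_group_detected_with_correct_pairs(self, rng):
        genes = ["POU5F1", "NANOG"]
        n = 6
        cols = {}
        groups = {}
        for g in ("UD", "FD", "T"):
            for i in range(n):
                s = f"{g}{i}"
                shift = 5.0 if g == "FD" else 0.0
                cols[s] = [8.0 + shift + rng.normal(0, 0.3),
                           7.0 + rng.normal(0, 0.3)]
                groups[s] = g
        m = pd.DataFrame(cols, index=genes)
        res = marker_anova(m, genes, groups)
        pou = res[res["gene"] == "POU5F1"]
        assert (pou["anova_p"] < 1e-3).all()
        for _, row in pou.iterrows():
            if "FD" in row["pair"]:
                assert row["tukey_p"] < 0.05
            else:
                assert row["tukey_p"] > 0.05

    def test_two_groups_tukey_agrees_with_anova_decision(self, rng):
        m = pd.DataFrame({f"a{i}": [rng.normal()] for i in range(5)} |
                         {f"b{i}": [rng.normal() + 4.0] for i in range(5)},
                         index=["SOX2"])
        groups = {c: c[0] for c in m.columns}
        res = marker_anova(m, ["SOX2"], groups)
        assert len(res) == 1
        assert (res["anova_p"] < 0.05).all() == (res["tukey_p"] < 0.05).all()

    def test_missing_gene_reported_not_fatal(self, rng):
        m = pd.DataFrame({"a0": [1.0], "a1": [1.1], "b0": [2.0], "b1": [2.1]},
                         index=["NES"])
        res = marker_anova(m, ["NES", "ABSENT"], {c: c[0] for c in m.columns})
        assert (res[res["gene"] == "ABSENT"]["status"] == "missing").all()
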