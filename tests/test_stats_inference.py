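"""Paired tests, repeated-measures ANOVA, outlier screen, corrections,
Spearman matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cyberface as cf
from cyberface.stats_inference import (
    DegenerateInputError,
    apply_transform,
    rm_anova_2way,
)

EM = list(cf.EMOTIONS)


class TestPairedT:
    def test_identical_pairs(self):
        res = cf.paired_t([1, 2, 3], [1, 2, 3])
        assert res.value == 0.0 and res.p == 1.0

    def test_direction(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=8)
        res = cf.paired_t(y + 1 + rng.normal(0, 1e-3, 8), y)
        assert res.value > 10 and res.p < 1e-6

    def test_constant_nonzero_differences_degenerate(self):
        with pytest.raises(DegenerateInputError):
            cf.paired_t([2, 3, 4, 5], [1, 2, 3, 4])

    def test_df_is_n_minus_1(self):
        rng = np.random.default_rng(1)
        res = cf.paired_t(rng.normal(size=14), rng.normal(size=14))
        assert res.df == 13


class TestWilcoxon:
    def test_all_zero_differences_flagged(self):
        res = cf.wilcoxon_paired([1.0, 2.0], [1.0, 2.0])
        assert res.value == 0.0 and res.p == 1.0 and res.note

    def test_maximal_shift_n14(self):
        """All 14 differences positive and distinct: Z is the maximum
        attainable and the approximate p is consistent with the exact
        signed-rank bound."""
        y = np.arange(1.0, 15.0)
        x = y + np.linspace(1.0, 2.0, 14)  # distinct positive differences
        res = cf.wilcoxon_paired(x, y)
        n = 14
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        z_max = (n * (n + 1) / 4) / sigma
        assert res.value == pytest.approx(z_max)  # positive: x exceeds y
        exact_p = 2 * 0.5**n  # both one-sided extremes
        assert res.p == pytest.approx(exact_p, abs=1e-3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=14), rng.normal(size=14)
        a = cf.wilcoxon_paired(x, y)
        b = cf.wilcoxon_paired(y, x)
        assert a.value == pytest.approx(-b.value)

    def test_agrees_with_exact_distribution_small_n(self):
        """Normal-approximation p stays close to the exact signed-rank p for
        n <= 15 (no ties)."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(10, 16)
            x = rng.normal(size=n)
            y = x + rng.normal(0.4, 1.0, size=n)
            approx = cf.wilcoxon_paired(x, y)
            exact = stats.wilcoxon(x, y, zero_method="wilcox", method="exact")
            assert approx.p == pytest.approx(exact.pvalue, abs=0.08)


class TestTransforms:
    def test_arcsinh_matches_numpy(self):
        v = np.array([0.0, 1.0, 100.0])
        assert apply_transform(v, "arcsinh") == pytest.approx(np.arcsinh(v))

    def test_ordered_quantile_is_monotone_and_normal_shaped(self):
        rng = np.random.default_rng(4)
        v = rng.exponential(size=200)
        z = apply_transform(v, "ordered-quantile")
        assert np.all(np.diff(z[np.argsort(v)]) >= 0)
        assert stats.shapiro(z).pvalue > 0.5  # rank-normalized by construction

    def test_yeo_johnson_reduces_skew(self):
        rng = np.random.default_rng(5)
        v = rng.lognormal(size=500)
        z = apply_transform(v, "yeo-johnson")
        assert abs(stats.skew(z)) < abs(stats.skew(v))


class TestOutliers:
    def test_hand_quartiles(self):
        rep = cf.identify_outliers([1, 2, 3, 4, 100])
        assert rep["value"].tolist() == [100.0]
        assert rep["bound"].tolist() == ["upper"]
        assert rep["threshold"].iloc[0] == pytest.approx(10.0)  # Q3 + 3*IQR

    def test_constant_vector_clean(self):
        assert len(cf.identify_outliers([5.0] * 10)) == 0

    def test_symmetric_data_clean(self):
        assert len(cf.identify_outliers([-2, -1, 0, 1, 2])) == 0

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        v = np.append(rng.normal(size=30), 50.0)
        a = cf.identify_outliers(v)
        b = cf.identify_outliers(v[::-1].copy())
        assert sorted(a["value"]) == sorted(b["value"])


class TestAdjustPvalues:
    def test_bh_hand_stepup(self):
        out = cf.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "benjamini-hochberg")
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bonferroni_multiplies(self):
        out = cf.adjust_pvalues([0.03] + [0.5] * 9, "bonferroni")
        assert out[0] == pytest.approx(0.30)

    def test_single_p_unchanged(self):
        for method in ("benjamini-hochberg", "bonferroni"):
            assert cf.adjust_pvalues([0.2], method)[0] == pytest.approx(0.2)

    def test_bh_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(7)
        p = rng.random(50)
        adj = cf.adjust_pvalues(p, "benjamini-hochberg")
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestRMAnova:
    @staticmethod
    def noise_table(rng, emotion="anger"):
        rows = [
            dict(subject=s, condition=c, segment=g, emotion=emotion,
                 auc=rng.normal(200, 50))
            for s in range(14)
            for c in ("inclusion", "exclusion")
            for g in (1, 2, 3)
        ]
        return pd.DataFrame(rows)

    def test_output_shape_and_dfs(self):
        res = rm_anova_2way(self.noise_table(np.random.default_rng(8)),
                            transforms={"anger": "none"})
        assert set(res["effect"]) == {"condition", "segment", "condition:segment"}
        assert res.set_index("effect").loc["condition", "DFn"] == 1
        assert res.set_index("effect").loc["condition", "DFd"] == 13
        assert (res.set_index("effect").loc[["segment", "condition:segment"], "DFd"] == 26).all()

    def test_location_and_scale_invariance_of_f(self):
        df = self.noise_table(np.random.default_rng(9))
        base = rm_anova_2way(df, transforms={"anger": "none"})
        shifted = df.copy()
        shifted["auc"] = shifted["auc"] * 3.0 + 1000.0
        res = rm_anova_2way(shifted, transforms={"anger": "none"})
        assert res["F"].to_numpy() == pytest.approx(base["F"].to_numpy())

    def test_unbalanced_design_rejected(self):
        df = self.noise_table(np.random.default_rng(10)).iloc[:-1]
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova_2way(df, transforms={"anger": "none"})

    def test_outlier_exclusion_drops_whole_subject(self):
        df = self.noise_table(np.random.default_rng(11))
        df.loc[(df.subject == 3) & (df.segment == 1) & (df.condition == "inclusion"),
               "auc"] = 1e5
        res = rm_anova_2way(df, transforms={"anger": "none"}, include_outliers=False)
        assert (res["n_subjects"] == 13).all()

    def test_adjustment_spans_all_emotions(self, cohort_series):
        from cyberface import auc_masking as am

        rows = []
        for (sid, cond), s in cohort_series.items():
            recs = am.segment_aucs(s)
            recs.insert(0, "subject", sid)
            recs.insert(1, "condition", cond)
            rows.append(recs)
        table = pd.concat(rows, ignore_index=True)
        seg = table[table.scope != "total"].copy()
        seg["segment"] = seg.scope.str.removeprefix("segment").astype(int)
        res = rm_anova_2way(seg[["subject", "condition", "segment", "emotion", "auc"]])
        assert len(res) == 21  # 7 emotions x 3 effects
        assert (res["p_adjusted"] >= res["p"] - 1e-12).all()


class TestSpearman:
    def test_perfect_monotone(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 4, 8, 16, 32]})
        out = cf.spearman_matrix(df)
        assert out["rho"].loc["a", "b"] == pytest.approx(1.0)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [7, 7, 7, 7]})
        out = cf.spearman_matrix(df)
        assert np.isnan(out["rho"].loc["a", "b"])
        assert len(out["constant_pairs"]) > 0

    def test_null_correlations_small(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.random((500, 2)), columns=["x", "y"])
        out = cf.spearman_matrix(df, correction=None)
        assert abs(out["rho"].loc["x", "y"]) < 0.1

    def test_cross_matrix_shape(self):
        rng = np.random.default_rng(13)
        left = pd.DataFrame(rng.random((20, 3)), columns=list("abc"))
        right = pd.DataFrame(rng.random((20, 2)), columns=list("xy"))
        out = cf.spearman_matrix(left, right)
        assert out["rho"].shape == (3, 2)
        assert (out["p_adjusted"].to_numpy() >= out["p"].to_numpy() - 1e-12).all()
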