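"""Statistical layer: exactness, levels, correction, and the results matrix."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import hrvaffect as hv
from hrvaffect import datasets
from hrvaffect.stats import (
    CONTRAST_ORDER, AffectContrastModel, ComparisonResult, bonferroni,
    build_results_table, demographics_t_test, effect_size_r, paired_wilcoxon,
    ranksum_wilcoxon, shapiro_wilk_screen,
)

from oracles import exact_rank_sum_p, exact_signed_rank_p


class TestShapiroScreen:
    def test_normal_data_passes_screen(self):
        rng = np.random.default_rng(0)
        hits = sum(shapiro_wilk_screen(rng.normal(size=500))[2]
                   for _ in range(100))
        assert hits >= 90

    def test_exponential_data_fails_screen(self):
        rng = np.random.default_rng(1)
        rejects = sum(not shapiro_wilk_screen(rng.exponential(size=500))[2]
                      for _ in range(100))
        assert rejects >= 99

    def test_n_out_of_range(self):
        with pytest.raises(ValueError):
            shapiro_wilk_screen(np.array([1.0, 2.0]))


class TestPairedWilcoxon:
    def test_identical_samples_degenerate(self):
        x = np.arange(10.0)
        z, p = paired_wilcoxon(x, x)
        assert z == 0.0 and p == 1.0

    def test_all_positive_n20_exact_tail(self):
        y = np.arange(20.0)
        z, p = paired_wilcoxon(y + 1.0, y)
        assert z > 0
        # two-sided exact tail: 2 * P(W = max) = 2 / 2^20
        assert p == pytest.approx(2 ** -19, rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 13))
        d = rng.normal(0.3, 1.0, size=n)
        x = rng.uniform(0, 10, size=n)
        _, p = paired_wilcoxon(x + d, x)
        assert p == pytest.approx(exact_signed_rank_p(list(d)), rel=1e-12)

    def test_scipy_cross_check_large_n(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        y = x + rng.normal(0.2, 1.0, size=60)
        z, p = paired_wilcoxon(x, y)
        ref = sstats.wilcoxon(x, y, zero_method="wilcox", correction=False,
                              method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_type_one_error_level(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            _, p = paired_wilcoxon(x, y)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_too_few_informative_pairs(self):
        with pytest.raises(ValueError):
            paired_wilcoxon(np.array([1, 2, 3, 4, 5.0]), np.zeros(5))


class TestRankSum:
    def test_identical_multisets(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        z, p = ranksum_wilcoxon(a, a.copy())
        assert z == 0.0 and p == 1.0

    def test_complete_separation_exact(self):
        a = np.arange(1.0, 11.0)
        b = np.arange(11.0, 21.0)
        z, p = ranksum_wilcoxon(a, b)
        assert z < 0  # group a has the smaller median
        from math import comb
        assert p == pytest.approx(2.0 / comb(20, 10), rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(size=6)
        b = rng.normal(0.8, 1.0, size=6)
        _, p = ranksum_wilcoxon(a, b)
        assert p == pytest.approx(exact_rank_sum_p(list(a), list(b)), rel=1e-9)

    def test_type_one_error_level(self):
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            _, p = ranksum_wilcoxon(rng.normal(size=30), rng.normal(size=30))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            ranksum_wilcoxon(np.arange(3.0), np.arange(10.0))


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        assert bonferroni([0.004], m=12) == [pytest.approx(0.048)]
        assert bonferroni([0.2], m=12) == [1.0]

    def test_monotone_and_order_preserving(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=20)
        out = bonferroni(p, m=12)
        assert all(c >= r for c, r in zip(out, p))
        assert np.argsort(out).tolist() == np.argsort(np.minimum(p * 12, 1)).tolist()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], m=3)


class TestEffectSize:
    def test_reported_magnitude_consistency(self):
        # Z=4.32 at window-level N=123 reproduces the r ~= 0.39 convention
        assert effect_size_r(4.32, 123) == pytest.approx(0.39, abs=0.005)

    def test_zero_z(self):
        assert effect_size_r(0.0, 50) == 0.0

    def test_agrees_with_rank_biserial_conversion(self):
        """r from Z agrees with an independent rank-biserial-to-r route on a
        small fully enumerable sample."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 8.0])
        b = np.array([5.0, 6.0, 7.0, 9.0, 10.0])
        z, _ = ranksum_wilcoxon(a, b)
        r_z = effect_size_r(z, a.size + b.size)
        # rank-biserial by direct pair counting, converted through
        # Z = rb * n1 * n2 / (2 sigma_U)
        u1 = sum(float(x > y) + 0.5 * float(x == y) for x in a for y in b)
        rb = 2.0 * u1 / (a.size * b.size) - 1.0
        n1, n2, nn = a.size, b.size, a.size + b.size
        sigma_u = np.sqrt(n1 * n2 * (nn + 1) / 12.0)
        r_rb = abs(rb) * n1 * n2 / (2.0 * sigma_u) / np.sqrt(nn)
        assert r_z == pytest.approx(r_rb, abs=0.02)


class TestDemographics:
    def test_patient_table_descriptives(self):
        ages = datasets.patient_ages()
        res = demographics_t_test(ages, ages + 0.5)
        desc = res.descriptives["a"]
        assert desc["mean"] == pytest.approx(35.00, abs=0.005)
        assert desc["sd_pop"] == pytest.approx(15.81, abs=0.005)
        assert desc["n"] == 11

    def test_identical_groups(self):
        res = demographics_t_test(np.full(5, 30.0), np.full(7, 30.0))
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_level_under_null(self):
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            res = demographics_t_test(rng.normal(size=17), rng.normal(size=11))
            rejections += res.p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


def _toy_long_table(seed=0, n_hc=8, delta=3.0):
    """Small normalized-value table with an HC-only condition effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, eff in (("HC", n_hc, delta), ("MCS", 5, 0.0), ("UWS", 6, 0.0)):
        for s in range(n):
            for w in range(6):
                for cond, shift in (("acquaintance", eff), ("stranger", 0.0)):
                    for feat in hv.FEATURE_NAMES:
                        val = rng.normal() + (shift if feat in ("MeanNN", "MedianNN") else 0.0)
                        rows.append((f"{group}{s}", group, f"w{w}:{cond[:3]}",
                                     cond, feat, val))
    return pd.DataFrame(rows, columns=["subject_id", "group", "window_id",
                                       "condition", "feature", "value"])


class TestModelAndResultsTable:
    def test_matrix_shape_and_order(self):
        res = AffectContrastModel.from_dataframe(_toy_long_table()).fit()
        mat = res.significance_matrix()
        assert mat.shape == (12, 9)
        assert list(mat.index) == list(hv.FEATURE_NAMES)
        assert tuple(mat.columns) == CONTRAST_ORDER

    def test_hc_only_effect_pattern(self):
        res = AffectContrastModel.from_dataframe(_toy_long_table(delta=3.0)).fit()
        assert res.get("MeanNN", "HC:acq-vs-str").significant
        assert not res.get("MeanNN", "UWS:acq-vs-str").significant
        assert not res.get("MeanNN", "MCS:acq-vs-str").significant

    def test_reported_medians_are_sample_medians(self):
        df = _toy_long_table()
        res = AffectContrastModel.from_dataframe(df).fit()
        c = res.get("SDNN", "HC-vs-MCS:acq")
        hc = df[(df.group == "HC") & (df.condition == "acquaintance")
                & (df.feature == "SDNN")]["value"]
        assert c.mdn1 == pytest.approx(float(np.median(hc)))
        assert c.n1 == len(hc)

    def test_null_cohort_family_control(self):
        spurious = 0
        cells = 0
        for seed in range(20):
            res = AffectContrastModel.from_dataframe(
                _toy_long_table(seed=seed, delta=0.0)).fit()
            for c in res.comparisons:
                cells += 1
                spurious += c.significant
        assert spurious / cells <= 0.05

    def test_empty_comparisons(self):
        assert build_results_table([]).empty

    def test_summary_mentions_significant_cell(self):
        res = AffectContrastModel.from_dataframe(_toy_long_table(delta=3.0)).fit()
        text = res.summary()
        assert "MeanNN" in text and "HC:acq-vs-str" in text

    def test_effect_size_uses_pooled_window_n(self):
        res = AffectContrastModel.from_dataframe(_toy_long_table(n_hc=17)).fit()
        c = res.get("MeanNN", "HC-vs-MCS:acq")
        assert c.n1 == 17 * 6 and c.n2 == 5 * 6
        assert c.r == pytest.approx(abs(c.statistic) / np.sqrt(c.n1 + c.n2))
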