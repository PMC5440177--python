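"""Test-retest metrics: TD, MA-TD, BS-CV, ICC, summaries, flags."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petquant import (PairedMeasurements, bs_cv, flag_outlier,
                      heterogeneity_ratio, icc_oneway, ma_td, round_half_up,
                      signed_td, summarize_by_region, td_category)
from petquant.reliability import SUMMARY_REGIONS


def pairs_of(test, retest):
    test = np.asarray(test, dtype=float)
    return PairedMeasurements(subjects=[f"s{i}" for i in range(test.size)],
                              test=test, retest=np.asarray(retest, float))


class TestSignedTD:
    def test_identical_values(self):
        assert signed_td(5.0, 5.0) == 0.0

    def test_arithmetic(self):
        assert signed_td(110.0, 90.0) == pytest.approx(20.0)

    def test_antisymmetry(self):
        assert signed_td(90.0, 110.0) == pytest.approx(-20.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(0.01, 1e6), st.floats(0.01, 1e6))
    def test_bounded_for_positive_values(self, a, b):
        td = signed_td(a, b)
        assert -200.0 < td < 200.0
        assert td == pytest.approx(-signed_td(b, a))


class TestMATD:
    def test_identical_pairs(self):
        value, cat = ma_td(pairs_of([1, 2, 3], [1, 2, 3]))
        assert value == 0.0 and cat == "low"

    def test_median_of_absolute_tds(self):
        # construct pairs whose |TD| are exactly {3,5,8,12,20}
        tds = np.array([3.0, 5, 8, 12, 20])
        test = 100 * (200 + tds) / (200 - tds)
        pairs = pairs_of(test, np.full(5, 100.0))
        value, cat = ma_td(pairs)
        assert value == pytest.approx(8.0)
        assert cat == "low"

    @pytest.mark.parametrize("v,cat", [
        (9.99, "low"), (10.0, "moderate"), (14.99, "moderate"),
        (15.0, "high"), (19.99, "high"), (20.0, "very high")])
    def test_category_boundaries(self, v, cat):
        assert td_category(v) == cat


class TestBSCV:
    def test_example(self):
        assert bs_cv(pairs_of([8, 10, 12], [8, 10, 12])) == pytest.approx(20.0)

    def test_constant_sessions(self):
        assert bs_cv(pairs_of([5, 5, 5], [7, 7, 7])) == 0.0

    def test_mean_of_session_cvs(self):
        p = pairs_of([8, 10, 12], [9, 10, 11])  # CVs 20 and 10
        assert bs_cv(p) == pytest.approx(15.0)

    def test_scale_invariance(self):
        p1 = pairs_of([8, 10, 12], [9, 11, 13])
        p2 = pairs_of([80, 100, 120], [90, 110, 130])
        assert bs_cv(p1) == pytest.approx(bs_cv(p2), rel=1e-12)


def icc_bruteforce(test, retest):
    """Independent one-way ANOVA by explicit sums of squares."""
    x = np.stack([np.asarray(test, float), np.asarray(retest, float)], axis=1)
    n, k = x.shape
    grand = x.mean()
    ss_total = np.sum((x - grand) ** 2)
    ss_bs = sum(k * (row.mean() - grand) ** 2 for row in x)
    ss_ws = ss_total - ss_bs
    ms_bs = ss_bs / (n - 1)
    ms_ws = ss_ws / (n * (k - 1))
    return (ms_bs - ms_ws) / (ms_bs + (k - 1) * ms_ws)


class TestICC:
    def test_perfect_retest(self):
        res = icc_oneway(pairs_of([10, 20, 30], [10, 20, 30]))
        assert res.icc == pytest.approx(1.0)

    def test_pure_noise_worst_case(self):
        # all subjects share one mean; only within-subject spread remains
        res = icc_oneway(pairs_of([9, 11, 10], [11, 9, 10]))
        assert res.icc <= 0.0

    def test_example_matches_bruteforce(self):
        t, r = [10, 20, 30, 40, 50], [12, 19, 33, 38, 52]
        res = icc_oneway(pairs_of(t, r))
        assert res.icc == pytest.approx(icc_bruteforce(t, r), abs=1e-12)

    def test_matches_pingouin_icc1(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        t, r = [10.0, 20, 30, 40, 50], [12.0, 19, 33, 38, 52]
        df = pd.DataFrame({
            "subject": list(range(5)) * 2,
            "session": ["test"] * 5 + ["retest"] * 5,
            "value": t + r})
        icc1 = pingouin.intraclass_corr(df, targets="subject", raters="session",
                                        ratings="value").set_index("Type")
        assert icc_oneway(pairs_of(t, r)).icc == pytest.approx(
            icc1.loc["ICC(1,1)", "ICC"], abs=1e-9)

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(st.integers(2, 10), st.integers(0, 2**31 - 1))
    def test_property_vs_bruteforce(self, n, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(1, 10, n)
        r = t + rng.normal(0, 1, n)
        if np.allclose(np.stack([t, r]), np.stack([t, r]).mean()):
            return
        res = icc_oneway(pairs_of(t, r))
        assert res.icc == pytest.approx(icc_bruteforce(t, r), abs=1e-12)


class TestSummaries:
    def test_half_up_rounding(self):
        assert round_half_up(0.825, 2) == 0.83
        assert round_half_up(10.5, 0) == 11.0
        assert round_half_up(0.824999, 2) == 0.82

    def test_identical_values(self):
        med, (q25, q75) = summarize_by_region(
            {r: 3.0 for r in SUMMARY_REGIONS})
        assert med == 3.0 and q25 == 3.0 and q75 == 3.0

    def test_missing_region_rejected(self):
        with pytest.raises(KeyError):
            summarize_by_region({"hippocampus": 1.0})

    @pytest.mark.parametrize("values,median,iqr", [
        # printed per-region ICCs: voxelwise spectral analysis
        ([0.91, 0.71, 0.89, 0.88, 0.90, 0.59], 0.89, (0.75, 0.90)),
        # printed per-region ICCs: regional SRTM with cerebellar reference
        ([0.59, 0.68, 0.95, 0.87, 0.74, 0.63], 0.71, (0.64, 0.84)),
    ])
    def test_published_summary_examples(self, values, median, iqr):
        vals = dict(zip(SUMMARY_REGIONS, values))
        med, (q25, q75) = summarize_by_region(vals, display_decimals=2)
        assert med == pytest.approx(median)
        assert (q25, q75) == pytest.approx(iqr)


class TestHeterogeneityAndFlags:
    @pytest.mark.parametrize("ratio,cat", [
        (2.0, "very high"), (1.8, "high"), (1.9, "high"),
        (1.5, "moderate"), (1.0, "low")])
    def test_ratio_categories(self, ratio, cat):
        r, c = heterogeneity_ratio(ratio, 1.0)
        assert r == pytest.approx(ratio) and c == cat

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity_ratio(2.0, 0.0)

    @pytest.mark.parametrize("value,ws,kind,flag", [
        (5.0, 20.0, "regional", False),
        (-0.1, 20.0, "regional", True),
        (5.0, 60.0, "regional", True),
        (5.0, 60.0, "voxelwise", False),
        (5.0, 120.0, "voxelwise", True),
        (0.0, 5.0, "voxelwise", True),
    ])
    def test_outlier_rule(self, value, ws, kind, flag):
        assert flag_outlier(value, ws, kind) is flag
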